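#!/usr/bin/env python
"""Switch-gene detection and recovery of the planted ground truth.

Runs the full network-cartography branch (filter -> signed Pearson
network -> k-means communities with scree-selected k -> Zg/Kpi/APCC ->
classification -> targeted-removal robustness) on the low-vs-high
contrast, compares the detected switch genes against the planted set,
and repeats the recovery over several seeds to report average precision
and recall.
"""

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from netswitch.cartography import run_swim, SwimParams
from netswitch.synthetic import generate_modular_expression, switch_recovery_config


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-seeds", type=int, default=5)
    ap.add_argument("--out-dir", type=Path, default=Path("results/03_switch"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    precision, recall = [], []
    for i in range(args.n_seeds):
        seed = args.seed + i
        matrix, truth = generate_modular_expression(
            switch_recovery_config(seed=seed))
        res = run_swim(matrix, ("low", "high"),
                       SwimParams(seed=seed, compute_robustness=(i == 0)))
        found, planted = set(res.switch_genes), truth.planted_switch_genes
        precision.append(len(found & planted) / len(found) if found else 1.0)
        recall.append(len(found & planted) / len(planted))
        if i == 0:
            res.cartography.to_csv(args.out_dir / "cartography.tsv",
                                   sep="\t", index_label="gene")
            if res.heatmap is not None:
                res.heatmap.to_csv(args.out_dir / "switch_heatmap.tsv",
                                   sep="\t", index_label="gene")
            for name, curve in (res.robustness or {}).items():
                curve.to_csv(args.out_dir /
                             f"robustness_{name.replace('-', '_')}.tsv",
                             sep="\t", index=False)
            sw = res.robustness.get("switch") if res.robustness else None
            print(f"seed {seed}: {len(found)} switch genes detected "
                  f"({sorted(found)}), network k = {res.communities.k}")
            if sw is not None:
                exits = int(((sw["apl_mean"] - sw["rand_mean"]).abs()
                             > 1.96 * sw["rand_sd"]).sum())
                print(f"  switch-removal curve leaves the random 95% band "
                      f"at {exits}/{len(sw)} grid points")

    print(f"recovery over {args.n_seeds} seeds: "
          f"precision {np.mean(precision):.2f}, recall {np.mean(recall):.2f}")
    print(f"wrote cartography, heatmap and robustness tables to {args.out_dir}")


if __name__ == "__main__":
    main()
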