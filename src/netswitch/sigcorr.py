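"""Rank-based directional overlap and correlation between two signatures.

Given two ranked, scored differential signatures over a shared measured
universe, the procedure scans Fisher exact tests over rank cutoffs of
both signatures (the deciles of each signature's length), separately for
the pooled concordant hypothesis (shared genes moving up-up or down-down)
and the pooled discordant hypothesis (up-down or down-up).  The reported
overlap p-value is the minimum over all tests, Bonferroni-corrected for
the number of cutoff pairs times the two hypotheses; the correlation sign
is +1 when the winning hypothesis is concordant and -1 when discordant.
This is a reimplementation of the published description of the
rank-based "Running Fisher" comparison; the commercial implementation's
exact grid and correction are proprietary, so results are not expected
to be bit-compatible with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class DirectionalCounts:
    """Exact 4-cell partition of shared genes by direction pair."""

    up_up: int = 0
    up_down: int = 0
    down_up: int = 0
    down_down: int = 0

    @property
    def total(self) -> int:
        return self.up_up + self.up_down + self.down_up + self.down_down

    @property
    def concordant(self) -> int:
        return self.up_up + self.down_down

    @property
    def discordant(self) -> int:
        return self.up_down + self.down_up

    def as_dict(self) -> dict[str, int]:
        return {"up_up": self.up_up, "up_down": self.up_down,
                "down_up": self.down_up, "down_down": self.down_down}


@dataclass
class OverlapReport:
    """Result of one signature-pair comparison."""

    universe_size: int
    counts: DirectionalCounts
    a_only: int
    shared: int
    b_only: int
    rf_p: float
    sign: int                     # +1 concordant, -1 discordant, 0 undefined
    best_cutoffs: tuple[int, int] | None
    best_hypothesis: str | None   # "concordant" | "discordant"
    n_tests: int = 0

    @property
    def neg_log10_rf_p(self) -> float:
        return -math.log10(self.rf_p) if self.rf_p > 0 else math.inf


def _check_universe(sig: pd.DataFrame, universe: set, label: str) -> None:
    outside = [g for g in sig.index if g not in universe]
    if outside:
        raise ValueError(f"signature {label} has genes outside the universe: "
                         f"{outside[:5]}")


def directional_overlap(sig_a: pd.DataFrame, sig_b: pd.DataFrame,
                        universe: Sequence[str]) -> DirectionalCounts:
    """Partition the shared genes of two signatures by (direction in A,
    direction in B).  Genes outside the universe are an error."""
    uni = set(universe)
    _check_universe(sig_a, uni, "A")
    _check_universe(sig_b, uni, "B")
    shared = sig_a.index.intersection(sig_b.index)
    counts = DirectionalCounts()
    for g in shared:
        da, db = sig_a.loc[g, "direction"], sig_b.loc[g, "direction"]
        if da == "up" and db == "up":
            counts.up_up += 1
        elif da == "up":
            counts.up_down += 1
        elif db == "up":
            counts.down_up += 1
        else:
            counts.down_down += 1
    return counts


def fisher_exact_enrichment(k: int, n_a: int, n_b: int, n: int) -> float:
    """One-sided overlap p-value P(X >= k) with X ~ Hypergeometric(n, n_a, n_b):
    the chance that two random subsets of sizes n_a, n_b drawn from a
    universe of n share at least k elements."""
    if not (0 <= k <= min(n_a, n_b) <= n and max(n_a, n_b) <= n):
        raise ValueError(f"impossible overlap counts: k={k}, nA={n_a}, "
                         f"nB={n_b}, N={n}")
    # canonical margin order: the test is symmetric in (n_a, n_b) and this
    # keeps it bit-identical under swapping the two signatures
    lo, hi = sorted((n_a, n_b))
    return float(hypergeom.sf(k - 1, n, hi, lo))


def _decile_cutoffs(n: int) -> list[int]:
    return sorted({max(1, math.ceil(n * i / 10)) for i in range(1, 11)})


def running_fisher(sig_a: pd.DataFrame, sig_b: pd.DataFrame,
                   universe: Sequence[str],
                   grid: tuple[Sequence[int], Sequence[int]] | None = None,
                   ) -> OverlapReport:
    """Directional rank-scan comparison of two signatures (see module
    docstring).  Empty signatures give the defined result rf_p = 1,
    sign = 0."""
    uni = list(universe)
    n_universe = len(uni)
    counts = directional_overlap(sig_a, sig_b, uni) \
        if len(sig_a) and len(sig_b) else DirectionalCounts()
    shared = len(sig_a.index.intersection(sig_b.index))
    venn = (len(sig_a) - shared, shared, len(sig_b) - shared)

    if len(sig_a) == 0 or len(sig_b) == 0:
        return OverlapReport(n_universe, counts, venn[0], venn[1], venn[2],
                             rf_p=1.0, sign=0, best_cutoffs=None,
                             best_hypothesis=None, n_tests=0)

    a_sorted = sig_a.sort_values("rank")
    b_sorted = sig_b.sort_values("rank")
    a_genes = a_sorted.index.to_numpy()
    b_genes = b_sorted.index.to_numpy()
    a_dir = a_sorted["direction"].to_numpy()
    b_dir = b_sorted["direction"].to_numpy()
    if grid is None:
        cut_a, cut_b = _decile_cutoffs(len(sig_a)), _decile_cutoffs(len(sig_b))
    else:
        cut_a, cut_b = list(grid[0]), list(grid[1])

    # collect every test, then pick the winner by a canonical key so the
    # result is independent of scan order and symmetric under swapping
    # the two signatures: smallest p, then largest overlap k, then
    # concordant before discordant, then the smaller cutoff pair
    tests = []
    for ca in cut_a:
        top_a = {g: d for g, d in zip(a_genes[:ca], a_dir[:ca])}
        for cb in cut_b:
            k_conc = k_disc = 0
            for g, db in zip(b_genes[:cb], b_dir[:cb]):
                da = top_a.get(g)
                if da is None:
                    continue
                if da == db:
                    k_conc += 1
                else:
                    k_disc += 1
            for hyp, k in (("concordant", k_conc), ("discordant", k_disc)):
                p = fisher_exact_enrichment(k, ca, cb, n_universe)
                tests.append((p, -k, hyp, min(ca, cb), max(ca, cb), (ca, cb)))
    n_tests = len(tests)
    p_min, neg_k, hyp, _, _, cut = min(tests)

    rf_p = min(1.0, p_min * n_tests)
    sign = +1 if hyp == "concordant" else -1
    return OverlapReport(n_universe, counts, venn[0], venn[1], venn[2],
                         rf_p=rf_p, sign=sign, best_cutoffs=cut,
                         best_hypothesis=hyp, n_tests=n_tests)


def correlation_panel(pa_tables: Mapping[str, pd.DataFrame],
                      disease_tables: Mapping[str, pd.DataFrame],
                      universe: Sequence[str]) -> pd.DataFrame:
    """All-pairs running-Fisher comparison between two families of
    signatures, returned as a tidy table (one row per pair) ready for
    TSV export or -log10(p) bar summaries."""
    rows = []
    for pa_name, pa in pa_tables.items():
        for dis_name, dis in disease_tables.items():
            rep = running_fisher(pa, dis, universe)
            rows.append({
                "pa": pa_name, "disease": dis_name,
                "sign": rep.sign, "rf_p": rep.rf_p,
                "neg_log10_rf_p": rep.neg_log10_rf_p,
                "a_only": rep.a_only, "shared": rep.shared,
                "b_only": rep.b_only,
                **rep.counts.as_dict(),
            })
    cols = ["pa", "disease", "sign", "rf_p", "neg_log10_rf_p",
            "a_only", "shared", "b_only",
            "up_up", "up_down", "down_up", "down_down"]
    return pd.DataFrame(rows, columns=cols)
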