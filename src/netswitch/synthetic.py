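"""Synthetic microarray-style data with known ground truth.

The generator emulates the structure the downstream stages assume:
log2-scale intensities with group structure (three activity levels by
default), planted correlated modules driven by latent factors, planted
anti-correlated inter-module "switch" nodes, planted differential
expression as group-specific mean shifts, paired signatures with
controlled directional concordance, random gene sets with a planted
enriched set, and regulator->target edges with a planted dominant
regulator.  Every generator is fully determined by its seed.

Factor model
------------
A gene in module m is ``a * f_m + noise_sd * eps`` with ``f_m`` a latent
per-sample standard-normal factor.  The loading is calibrated as
``a = noise_sd * sqrt(r / (1 - r))`` so the expected within-module
pairwise Pearson correlation is exactly ``r = a^2 / (a^2 + noise_sd^2)``.
Module factors are equicorrelated (``factor_corr``), modelling related
pathway activity: this is what lets a planted switch gene — equal
negative loadings on each of its foreign factors, near-zero loading on
its own module — reach edge-strength anti-correlation with *several*
foreign modules at once and act as a genuine inter-module connector.
With independent factors a two-factor loader's cross-module correlation
is capped at ``r/sqrt(2)``, below any realistic edge threshold, and the
planted "switch" would merely dangle off a single module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import bh_fdr, rank_and_score
from .io_formats import ExpressionMatrix, GeneSetCollection

# switch loadings, relative to the module loading a:
# each foreign factor -0.8a, own factor +0.083a.
_SWITCH_FOREIGN = 0.8
_SWITCH_OWN = 0.083


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the modular expression generator.

    ``n_modules * module_size + n_switch`` genes are planted; the rest are
    unstructured filler (pure noise around their baseline).  ``de_genes``
    lists planted shifts as (gene, group, log2fc) triples applied on the
    log2 scale before exponentiation.
    """

    n_genes: int = 100
    n_samples_per_group: int = 20
    groups: tuple[str, ...] = ("low", "moderate", "high")
    n_modules: int = 3
    module_size: int = 30
    within_module_r: float = 0.8
    n_switch: int = 5
    switch_foreign_modules: int = 2
    de_genes: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float = 0.5
    factor_corr: float = 0.3
    baseline_range: tuple[float, float] = (5.0, 9.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size + self.n_switch > self.n_genes:
            raise ValueError("n_modules*module_size + n_switch exceeds n_genes")
        if not (0.0 < self.within_module_r < 1.0):
            raise ValueError("within_module_r must lie in (0, 1)")
        if not (0.0 <= self.factor_corr < 1.0):
            raise ValueError("factor_corr must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_switch > 0:
            if self.switch_foreign_modules < 2:
                raise ValueError("switch_foreign_modules must be >= 2")
            if self.switch_foreign_modules > self.n_modules - 1:
                raise ValueError("switch_foreign_modules exceeds available "
                                 "foreign modules (n_modules - 1)")
        if self.n_samples_per_group < 2 or not self.groups:
            raise ValueError("need >= 2 samples per group and >= 1 group")


@dataclass
class GroundTruth:
    """What was planted: module membership, switch genes, DE shifts."""

    module_of_gene: dict[str, int]
    planted_switch_genes: set[str]
    planted_de: dict[str, tuple[str, float]]
    switch_plan: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "module_of_gene": self.module_of_gene,
            "planted_switch_genes": sorted(self.planted_switch_genes),
            "planted_de": {g: list(v) for g, v in self.planted_de.items()},
            "switch_plan": self.switch_plan,
        }


def gene_layout(config: SynthConfig) -> tuple[dict[str, int], dict[str, dict[str, int]], list[str]]:
    """Deterministic gene-id layout shared by the generator and DE planner.

    Returns (module_of_gene, switch_plan, filler_genes).  Module genes are
    named ``M{m}G{j:03d}``, switch genes ``SW{i:02d}``, filler ``F{j:03d}``.
    Switch gene i nominally belongs to module ``i % n_modules`` and its
    foreign factors are taken in cyclic order starting from the next
    module.
    """
    module_of: dict[str, int] = {}
    for m in range(config.n_modules):
        for j in range(config.module_size):
            module_of[f"M{m}G{j:03d}"] = m
    plan: dict[str, dict] = {}
    for i in range(config.n_switch):
        own = i % config.n_modules
        foreign = [(own + 1 + k) % config.n_modules
                   for k in range(config.n_modules - 1)][:config.switch_foreign_modules]
        plan[f"SW{i:02d}"] = {"own": own, "foreign": foreign}
    n_filler = config.n_genes - len(module_of) - len(plan)
    filler = [f"F{j:03d}" for j in range(n_filler)]
    return module_of, plan, filler


def generate_modular_expression(config: SynthConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate a linear-scale intensity matrix with planted structure.

    Values are built on the log2 scale (factors + noise + DE shifts +
    per-gene baseline) and exponentiated, so all intensities are strictly
    positive and a planted log2FC is recovered exactly when noise_sd = 0.
    """
    rng = np.random.default_rng(config.seed)
    module_of, plan, filler = gene_layout(config)
    genes = list(module_of) + list(plan) + filler
    samples = [f"S{g}{i:02d}" for g in range(len(config.groups))
               for i in range(config.n_samples_per_group)]
    group_labels = [config.groups[g] for g in range(len(config.groups))
                    for _ in range(config.n_samples_per_group)]
    sample_group = pd.Series(group_labels, index=samples, dtype=object)
    n_samples = len(samples)

    r = config.within_module_r
    a = config.noise_sd * math.sqrt(r / (1.0 - r))
    # equicorrelated unit-variance factors: shared + idiosyncratic parts
    rho = config.factor_corr
    shared = rng.standard_normal(n_samples)
    idio = rng.standard_normal((config.n_modules, n_samples))
    factors = math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * idio
    baseline = rng.uniform(*config.baseline_range, size=len(genes))

    log2vals = np.zeros((len(genes), n_samples))
    for gi, gene in enumerate(genes):
        noise = config.noise_sd * rng.standard_normal(n_samples)
        if gene in module_of:
            signal = a * factors[module_of[gene]]
        elif gene in plan:
            p = plan[gene]
            signal = _SWITCH_OWN * a * factors[p["own"]]
            for fm in p["foreign"]:
                signal = signal - _SWITCH_FOREIGN * a * factors[fm]
        else:
            signal = 0.0
        log2vals[gi] = baseline[gi] + signal + noise

    planted_de: dict[str, tuple[str, float]] = {}
    gene_index = {g: i for i, g in enumerate(genes)}
    group_cols = {g: [i for i, lbl in enumerate(group_labels) if lbl == g]
                  for g in config.groups}
    for gene, group, lfc in config.de_genes:
        if gene not in gene_index:
            raise ValueError(f"de_genes names unknown gene {gene!r}")
        if group not in group_cols:
            raise ValueError(f"de_genes names unknown group {group!r}")
        log2vals[gene_index[gene], group_cols[group]] += lfc
        planted_de[gene] = (group, lfc)

    values = pd.DataFrame(np.exp2(log2vals), index=genes, columns=samples)
    truth = GroundTruth(module_of_gene=dict(module_of),
                        planted_switch_genes=set(plan),
                        planted_de=planted_de,
                        switch_plan=plan)
    return ExpressionMatrix(values, sample_group, is_log2=False), truth


def plan_module_de(config: SynthConfig, log2fc: float = 1.5,
                   group: str | None = None) -> tuple[tuple[str, str, float], ...]:
    """Module-consistent DE plan used by the switch-recovery experiments.

    Every module gene is shifted by +log2fc in ``group`` (default: the
    last, highest-activity group) and every switch gene by -log2fc: a
    switch opposes *all* the modules it connects, and a single shift can
    only oppose module shifts that share a sign, so module shifts are
    kept uniform.  Filler genes get no shift and are removed by the
    significance filter.
    """
    if group is None:
        group = config.groups[-1]
    module_of, plan, _ = gene_layout(config)
    de: list[tuple[str, str, float]] = []
    for gene in module_of:
        de.append((gene, group, log2fc))
    for gene in plan:
        de.append((gene, group, -log2fc))
    return tuple(de)


def switch_recovery_config(seed: int = 0, log2fc: float = 1.5,
                           **overrides) -> SynthConfig:
    """The study condition for parameter-recovery runs: generator defaults
    plus the module-consistent DE plan, so the full pipeline (significance
    filter -> network -> cartography) can be exercised end to end."""
    base = SynthConfig(seed=seed, **overrides)
    return replace(base, de_genes=plan_module_de(base, log2fc=log2fc))


# ---------------------------------------------------------------------------
# signature pairs
# ---------------------------------------------------------------------------

def signature_universe(n_universe: int) -> list[str]:
    return [f"U{i:05d}" for i in range(n_universe)]


def generate_signature_pair(n_universe: int, n_sig: int,
                            overlap_fraction: float, concordance: float,
                            seed: int = 0):
    """Two ranked, scored signatures with controlled overlap and direction
    concordance.

    Exactly ``round(overlap_fraction * n_sig)`` genes are shared; among
    them exactly ``round(concordance * shared)`` have the same direction
    in both signatures.  Fold changes and p-values are sampled so every
    signature gene passes the p <= 0.05, |FC| >= 1.2 significance filter.

    Returns (table_a, table_b, truth) where truth records the shared,
    concordant and discordant gene lists and the universe size.
    """
    if not (0 <= overlap_fraction <= 1) or not (0 <= concordance <= 1):
        raise ValueError("overlap_fraction and concordance must lie in [0, 1]")
    if n_sig > n_universe:
        raise ValueError("n_sig exceeds n_universe")
    n_shared = int(round(overlap_fraction * n_sig))
    if 2 * n_sig - n_shared > n_universe:
        raise ValueError("universe too small for two signatures with this overlap")
    rng = np.random.default_rng(seed)
    universe = signature_universe(n_universe)
    picked = rng.choice(n_universe, size=2 * n_sig - n_shared, replace=False)
    shared = [universe[i] for i in picked[:n_shared]]
    a_only = [universe[i] for i in picked[n_shared:n_sig]]
    b_only = [universe[i] for i in picked[n_sig:]]

    def _sample_stats(n: int) -> tuple[np.ndarray, np.ndarray]:
        mag = rng.uniform(math.log2(1.2), 2.5, size=n)
        p = 10.0 ** rng.uniform(-8.0, math.log10(0.05), size=n)
        return mag, p

    genes_a = shared + a_only
    genes_b = shared + b_only
    dir_a = rng.choice([1.0, -1.0], size=len(genes_a))
    n_conc = int(round(concordance * n_shared))
    conc_idx = rng.permutation(n_shared)[:n_conc]
    flip = -np.ones(n_shared)
    flip[conc_idx] = 1.0
    dir_b = np.concatenate([dir_a[:n_shared] * flip,
                            rng.choice([1.0, -1.0], size=len(b_only))])

    def _table(genes: list[str], dirs: np.ndarray) -> pd.DataFrame:
        mag, p = _sample_stats(len(genes))
        tab = pd.DataFrame({"log2fc": dirs * mag, "p": p}, index=genes)
        tab["q"] = bh_fdr(tab["p"].to_numpy())
        return rank_and_score(tab)

    table_a = _table(genes_a, dir_a)
    table_b = _table(genes_b, dir_b)
    concordant = [shared[i] for i in sorted(conc_idx)]
    truth = {
        "n_universe": n_universe,
        "shared": shared,
        "concordant": concordant,
        "discordant": [g for g in shared if g not in set(concordant)],
    }
    return table_a, table_b, truth


# ---------------------------------------------------------------------------
# gene sets and TF edges
# ---------------------------------------------------------------------------

def generate_gene_sets(universe: Sequence[str], n_sets: int,
                       size_range: tuple[int, int],
                       planted: tuple[str, Sequence[str]] | None = None,
                       seed: int = 0) -> GeneSetCollection:
    """Random gene sets plus an optional planted set given verbatim.

    Random set sizes are drawn uniformly from ``size_range``
    (inclusive); members are sampled without replacement from the
    universe.  The planted set's members must lie in the universe.
    """
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size_range")
    if hi > len(universe):
        raise ValueError("size_range exceeds universe size")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    if planted is not None:
        name, genes = planted
        genes = list(genes)
        missing = [g for g in genes if g not in set(universe)]
        if missing:
            raise ValueError(f"planted genes outside universe: {missing[:5]}")
        sets[name] = genes
        desc[name] = "planted"
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        sets[f"SET{i:03d}"] = [universe[j] for j in members]
        desc[f"SET{i:03d}"] = "random"
    return GeneSetCollection(sets, desc)


def generate_tf_edges(query_genes: Sequence[str], universe: Sequence[str],
                      n_tfs: int = 10, targets_per_tf: int = 15,
                      planted_tf: str = "TF_PLANTED", seed: int = 0) -> pd.DataFrame:
    """Regulator->target edges with one planted dominant regulator.

    The planted TF targets every query gene with scores passing the
    default filters (signal < 500, regulatory potential < 1); background
    TFs pick random targets from the universe with scores straddling the
    filters, so filtering is actually exercised.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    records = []
    for g in query_genes:
        records.append((planted_tf, g, float(rng.uniform(10, 490)),
                        float(rng.uniform(0.05, 0.95))))
    for i in range(n_tfs):
        tf = f"TF{i:03d}"
        targets = rng.choice(len(universe), size=min(targets_per_tf, len(universe)),
                             replace=False)
        for j in targets:
            records.append((tf, universe[j], float(rng.uniform(10, 990)),
                            float(rng.uniform(0.05, 1.9))))
    return pd.DataFrame(records, columns=["tf", "target", "signal",
                                          "regulatory_potential"])
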