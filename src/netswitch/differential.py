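"""Preprocessing filters and two-group differential expression.

This module feeds both analysis branches: the network branch keeps genes
with |fold change| >= 1.5 and FDR q <= 0.05 before the co-expression
network is built, and the signature branch keeps genes with raw p <= 0.05
and |fold change| >= 1.2, ranks them by significance and assigns each a
100-1 score whose normalization (rank/N) makes signatures comparable
across platforms of different sizes.

A "differential table" throughout the package is a DataFrame indexed by
gene with columns ``log2fc``, ``p``, ``q``, ``rank``, ``score`` and
``direction`` ("up"/"down").
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

TABLE_COLUMNS = ["log2fc", "p", "q", "rank", "score", "direction"]


def bsce_preprocess(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Signal-intensity preprocessing for the signature branch.

    Non-positive values are floored to the dataset's smallest positive
    value (zeros are floored too, so the final log2 stays defined), genes
    whose mean intensity falls below the 20th percentile of the gene-mean
    distribution are removed, and log2 is applied last.
    """
    if matrix.is_log2:
        raise ValueError("bsce_preprocess expects a linear-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    positive = vals[vals > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive values; cannot floor negatives")
    floor = positive.min()
    vals = np.where(vals <= 0, floor, vals)
    floored = pd.DataFrame(vals, index=matrix.values.index,
                           columns=matrix.values.columns)
    gene_means = floored.mean(axis=1)
    cutoff = np.percentile(gene_means.to_numpy(), 20)
    keep = gene_means >= cutoff
    kept = floored.loc[keep]
    log.info("bsce_preprocess: floored %d non-positive entries, removed %d/%d "
             "low-intensity genes", int((matrix.values.to_numpy() <= 0).sum()),
             int((~keep).sum()), len(keep))
    return ExpressionMatrix(np.log2(kept), matrix.sample_group, is_log2=True)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(matrix: ExpressionMatrix, group_a: str,
                            group_b: str) -> pd.DataFrame:
    """Two-group contrast: log2fc = mean(B) - mean(A), Welch t-test p, BH q.

    The matrix must be on the log2 scale and each group must contribute at
    least two samples.  Genes with zero variance in both groups (Welch t
    undefined) get p = 1.
    """
    if not matrix.is_log2:
        raise ValueError("differential_expression expects a log2-scale matrix "
                         "(use ExpressionMatrix.to_log2 or bsce_preprocess)")
    cols_a = matrix.samples_in_group(group_a)
    cols_b = matrix.samples_in_group(group_b)
    for name, cols in ((group_a, cols_a), (group_b, cols_b)):
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has {len(cols)} samples; need >= 2")
    a = matrix.values[cols_a].to_numpy(dtype=float)
    b = matrix.values[cols_b].to_numpy(dtype=float)
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    table = pd.DataFrame({"log2fc": log2fc, "p": p}, index=matrix.values.index)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return rank_and_score(table)


def rank_and_score(table: pd.DataFrame) -> pd.DataFrame:
    """Assign significance ranks 1..N and the 100-1 score.

    Rank ascending by p; ties broken by larger |log2fc| first, then by
    gene id, so runs are fully reproducible.  The score for rank r of N is
    ceil(100 * (N - r + 1) / N): the top gene always scores 100 and the
    bottom gene at least 1.  Because the rank enters only through r/N,
    the score is invariant to platform size.
    """
    table = table.copy()
    n = len(table)
    if n == 0:
        for col in ("rank", "score"):
            table[col] = pd.Series(dtype=int)
        table["direction"] = pd.Series(dtype=object)
        return table[[c for c in TABLE_COLUMNS if c in table.columns]]
    gene_ids = table.index.astype(str).to_numpy()
    order = np.lexsort((gene_ids, -np.abs(table["log2fc"].to_numpy()),
                        table["p"].to_numpy()))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    table["rank"] = rank
    table["score"] = np.ceil(100.0 * (n - rank + 1) / n).astype(int).clip(1, 100)
    table["direction"] = np.where(table["log2fc"].to_numpy() < 0, "down", "up")
    cols = [c for c in TABLE_COLUMNS if c in table.columns]
    return table[cols + [c for c in table.columns if c not in cols]]


def swim_filter(table: pd.DataFrame, fc_cutoff: float = 1.5,
                alpha: float = 0.05) -> list[str]:
    """Genes retained for the network stage: |linear FC| >= fc_cutoff
    (i.e. |log2fc| >= log2 fc_cutoff) and FDR q <= alpha."""
    keep = (np.abs(table["log2fc"]) >= math.log2(fc_cutoff)) & (table["q"] <= alpha)
    return list(table.index[keep])


def bsce_signature(table: pd.DataFrame, p_max: float = 0.05,
                   fc_min: float = 1.2) -> pd.DataFrame:
    """Filter to the significant signature (raw p <= p_max and
    |linear FC| >= fc_min), then re-rank and re-score within it.

    An empty post-filter signature is flagged with a warning, not fatal.
    """
    keep = (table["p"] <= p_max) & (np.abs(table["log2fc"]) >= math.log2(fc_min))
    sig = table.loc[keep, ["log2fc", "p"]].copy()
    if sig.empty:
        log.warning("bsce_signature: no genes pass p <= %g, |FC| >= %g",
                    p_max, fc_min)
        return rank_and_score(sig)
    sig["q"] = bh_fdr(sig["p"].to_numpy())
    return rank_and_score(sig)


def meta_rank(tables: Sequence[pd.DataFrame],
              names: Sequence[str] | None = None) -> pd.DataFrame:
    """Rank genes by significance and directional consistency across datasets.

    Each gene's meta-score sums its per-dataset 100-1 scores signed by
    agreement with its majority direction (+score if the gene moves with
    the majority, -score otherwise).  Majority ties are broken by the
    larger summed score, then "up".  Genes are returned sorted by
    meta-score descending, gene id ascending.
    """
    if len(tables) == 0:
        raise ValueError("meta_rank needs at least one table")
    if names is None:
        names = [f"dataset{i + 1}" for i in range(len(tables))]
    entries: dict[str, list[tuple[str, int, str]]] = {}
    for name, tab in zip(names, tables):
        for gene, row in tab.iterrows():
            entries.setdefault(str(gene), []).append(
                (name, int(row["score"]), str(row["direction"])))
    records = []
    for gene, hits in entries.items():
        n_up = sum(1 for _, _, d in hits if d == "up")
        n_down = len(hits) - n_up
        if n_up != n_down:
            majority = "up" if n_up > n_down else "down"
        else:
            score_up = sum(s for _, s, d in hits if d == "up")
            score_down = sum(s for _, s, d in hits if d == "down")
            majority = "up" if score_up >= score_down else "down"
        meta = sum(s if d == majority else -s for _, s, d in hits)
        records.append({
            "gene": gene,
            "meta_score": meta,
            "n_datasets": len(hits),
            "majority_direction": majority,
            "directions": ",".join(f"{n}:{d}" for n, _, d in hits),
        })
    out = pd.DataFrame(records).set_index("gene")
    return out.sort_values(["meta_score", "gene"], ascending=[False, True])
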