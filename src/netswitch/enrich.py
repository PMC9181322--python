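"""Directional gene-set enrichment and regulator ranking.

Gene-set enrichment is the hypergeometric upper tail of the overlap
between a query list and each set, restricted to sets whose size (after
intersection with the measured universe) lies in [10, 500], with BH
correction across the tested sets.  The directional variant runs the two
opposite-direction partitions of a signature pair (up in one, down in
the other) through the same test.  Regulator ranking filters a
TF->target edge list by peak-signal and regulatory-potential caps and
orders TFs by degree into the query, breaking ties by betweenness
centrality in the filtered bipartite graph.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .differential import bh_fdr
from .io_formats import GeneSetCollection
from .sigcorr import fisher_exact_enrichment

log = logging.getLogger(__name__)


def gene_set_enrichment(query: Sequence[str], universe: Sequence[str],
                        collection: GeneSetCollection,
                        min_size: int = 10, max_size: int = 500,
                        direction_label: str = "") -> pd.DataFrame:
    """Hypergeometric enrichment of ``query`` against each eligible set.

    Sets are intersected with the universe before the size check; only
    sets with min_size <= size <= max_size are tested.  Returns one row
    per tested set with overlap, sizes, p and BH q, sorted by p then set
    name.  An empty query is an error; a query gene outside the universe
    is an error.
    """
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query")
    uni = set(universe)
    outside = sorted(query_set - uni)
    if outside:
        raise ValueError(f"query genes outside universe: {outside[:5]}")
    n, n_query = len(uni), len(query_set)
    rows = []
    for name, genes in collection:
        members = set(genes) & uni
        size = len(members)
        if not (min_size <= size <= max_size):
            continue
        k = len(members & query_set)
        p = fisher_exact_enrichment(k, size, n_query, n)
        rows.append({"set": name, "overlap": k, "set_size": size,
                     "query_size": n_query, "universe_size": n, "p": p})
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                      "query_size", "universe_size", "p"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    out["direction"] = direction_label
    return out.sort_values(["p", "set"]).reset_index(drop=True)


def directional_partition_enrichment(sig_pa: pd.DataFrame,
                                     sig_disease: pd.DataFrame,
                                     collection: GeneSetCollection,
                                     universe: Sequence[str],
                                     min_size: int = 10,
                                     max_size: int = 500,
                                     ) -> dict[str, pd.DataFrame]:
    """Enrichment of the two opposite-direction partitions of a pair.

    Partitions: genes up in the first signature and down in the second
    (``up_pa_down_disease``) and the reverse (``down_pa_up_disease``).
    Empty partitions yield empty result frames (logged).  Partition sizes
    sum to the discordant overlap count of the pair.
    """
    shared = sig_pa.index.intersection(sig_disease.index)
    up_down = [g for g in shared
               if sig_pa.loc[g, "direction"] == "up"
               and sig_disease.loc[g, "direction"] == "down"]
    down_up = [g for g in shared
               if sig_pa.loc[g, "direction"] == "down"
               and sig_disease.loc[g, "direction"] == "up"]
    results: dict[str, pd.DataFrame] = {}
    for label, genes in (("up_pa_down_disease", up_down),
                         ("down_pa_up_disease", down_up)):
        if not genes:
            log.info("partition %s is empty; no enrichment run", label)
            results[label] = pd.DataFrame(
                columns=["set", "overlap", "set_size", "query_size",
                         "universe_size", "p", "q", "direction"])
            continue
        results[label] = gene_set_enrichment(genes, universe, collection,
                                             min_size=min_size,
                                             max_size=max_size,
                                             direction_label=label)
    return results


def tf_rank(edges: pd.DataFrame, query_genes: Sequence[str],
            signal_max: float = 500.0, rp_max: float = 1.0) -> pd.DataFrame:
    """Rank regulators over a user-supplied TF->target edge list.

    Edges must carry a ``regulatory_potential`` column and may carry a
    ``signal`` column; an edge survives iff signal < signal_max (where
    signal is present) and regulatory_potential < rp_max (strict caps).
    The surviving edges restricted to the query genes form a bipartite
    graph; TFs are ranked by degree (number of distinct query targets),
    ties broken by betweenness centrality in that graph, then by name.
    """
    if "regulatory_potential" not in edges.columns:
        raise ValueError("edge table lacks a regulatory_potential column")
    keep = edges["regulatory_potential"] < rp_max
    if "signal" in edges.columns:
        signal = edges["signal"]
        keep &= signal.isna() | (signal < signal_max)
    filtered = edges.loc[keep]
    query = set(query_genes)
    filtered = filtered[filtered["target"].isin(query)]
    if filtered.empty:
        log.warning("tf_rank: no edges survive the score filters")
        return pd.DataFrame(columns=["tf", "degree", "betweenness", "targets"])

    graph = nx.Graph()
    for tf, target in filtered[["tf", "target"]].itertuples(index=False):
        graph.add_edge(f"tf::{tf}", f"g::{target}")
    betweenness = nx.betweenness_centrality(graph)

    rows = []
    for tf, grp in filtered.groupby("tf"):
        targets = sorted(set(grp["target"]))
        rows.append({"tf": tf, "degree": len(targets),
                     "betweenness": betweenness[f"tf::{tf}"],
                     "targets": ",".join(targets)})
    out = pd.DataFrame(rows)
    out = out.sort_values(["degree", "betweenness", "tf"],
                          ascending=[False, False, True]).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
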