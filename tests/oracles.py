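"""Independent brute-force oracles used only by the tests.

Each function implements its definition directly (enumeration, step-up
recursion, Floyd-Warshall) without touching the package's code paths, so
agreement is a genuine cross-check.
"""

from fractions import Fraction
from math import comb

import numpy as np


def bh_stepup(pvalues):
    """Benjamini-Hochberg by the textbook step-up definition:
    q_i = min over j with p_j >= p_i of (m * p_j / rank_j), clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running_min = np.inf
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running_min = min(running_min, m * p[order[i]] / rank)
        q_sorted[i] = min(1.0, running_min)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_upper_tail(k, n_a, n_b, n):
    """Exact P(X >= k) for X ~ Hypergeometric(n, n_a, n_b) by summing the
    pmf over all attainable overlap counts, in exact rational arithmetic."""
    total = Fraction(0)
    denom = comb(n, n_b)
    for j in range(k, min(n_a, n_b) + 1):
        if n_b - j > n - n_a:
            continue
        total += Fraction(comb(n_a, j) * comb(n - n_a, n_b - j), denom)
    return float(total)


def floyd_warshall_apl(adjacency):
    """Average shortest path of the largest connected component via
    Floyd-Warshall on a dense adjacency matrix (small graphs only)."""
    n = len(adjacency)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[adjacency > 0] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    # components = groups of mutually reachable nodes
    best_nodes, seen = [], set()
    for i in range(n):
        if i in seen:
            continue
        members = [j for j in range(n) if np.isfinite(dist[i, j])]
        seen.update(members)
        if len(members) > len(best_nodes):
            best_nodes = members
    if len(best_nodes) < 2:
        return 0.0
    sub = dist[np.ix_(best_nodes, best_nodes)]
    m = len(best_nodes)
    return float(sub.sum() / (m * (m - 1)))
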