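"""Co-expression network heat cartography and switch-gene detection.

The stages mirror the switch-gene procedure used throughout the package:

1. keep significantly differential genes (|FC| >= 1.5, q <= 0.05),
2. build a signed Pearson co-expression network (edge iff |r| >= threshold),
3. find communities by k-means on standardized expression profiles, with
   the cluster count chosen from the scree of the SSE curve,
4. compute per-node coordinates: within-module degree z-score Zg, the
   clusterphobic coefficient Kpi = 1 - (k_in / k_tot)^2, and the average
   Pearson correlation of a node with its neighbors (APCC, the mean
   incident edge weight),
5. classify nodes: hubs have Zg > 5; date/party/fight-club roles follow
   APCC (negative APCC = fight-club); switch genes are the fight-club
   nodes in region R4 of the (Kpi, Zg) plane: Zg < 2.5, Kpi > 0.8,
   APCC < 0,
6. probe robustness by targeted node removal, tracking the average
   shortest path of the largest connected component against a random-
   removal baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _average_linkage, leaves_list
from scipy.sparse import csgraph
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .differential import differential_expression, swim_filter
from .io_formats import ExpressionMatrix

log = logging.getLogger(__name__)

ROLE_FIGHT_CLUB = "fight-club"
ROLE_DATE = "date"
ROLE_PARTY = "party"


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_correlation_network(matrix: ExpressionMatrix, genes: Sequence[str],
                              r_threshold: float = 0.7) -> nx.Graph:
    """Signed Pearson co-expression network over ``genes``.

    An edge joins genes i, j iff |r_ij| >= r_threshold; the weight keeps
    the sign of r so the mean incident weight (APCC) can be negative.
    Constant genes cannot be correlated and are excluded with a warning;
    isolated nodes are retained and flagged with the node attribute
    ``isolated``.
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    sub = matrix.to_log2() if not matrix.is_log2 else matrix
    sub = sub.subset_genes(genes)
    vals = sub.values.to_numpy(dtype=float)
    sds = vals.std(axis=1)
    constant = sds == 0
    if constant.any():
        dropped = [g for g, c in zip(sub.genes, constant) if c]
        log.warning("excluding %d constant gene(s) from the network: %s",
                    len(dropped), dropped[:5])
    kept = [g for g, c in zip(sub.genes, constant) if not c]
    vals = vals[~constant]

    graph = nx.Graph(r_threshold=float(r_threshold))
    graph.add_nodes_from(kept)
    if len(kept) >= 2:
        corr = np.corrcoef(vals)
        ii, jj = np.triu_indices(len(kept), k=1)
        strong = np.abs(corr[ii, jj]) >= r_threshold
        graph.add_weighted_edges_from(
            (kept[i], kept[j], float(corr[i, j]))
            for i, j in zip(ii[strong], jj[strong]))
    for node in graph.nodes:
        graph.nodes[node]["isolated"] = graph.degree(node) == 0
    return graph


def threshold_for_density(matrix: ExpressionMatrix, genes: Sequence[str],
                          density: float) -> float:
    """Alternative edge-threshold mode: the |r| cutoff that yields the
    requested edge density (fraction of gene pairs connected)."""
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    sub = (matrix.to_log2() if not matrix.is_log2 else matrix).subset_genes(genes)
    vals = sub.values.to_numpy(dtype=float)
    vals = vals[vals.std(axis=1) > 0]
    corr = np.corrcoef(vals)
    ii, jj = np.triu_indices(len(corr), k=1)
    absr = np.sort(np.abs(corr[ii, jj]))
    k = max(1, int(round(density * absr.size)))
    return float(absr[-k])


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

@dataclass
class CommunityResult:
    assignment: pd.Series         # node -> module id at the selected k
    sse_curve: dict[int, float]   # k -> lowest SSE among replicates
    k: int


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def kmeans_communities(matrix: ExpressionMatrix, nodes: Sequence[str],
                       k_min: int = 2, k_max: int | None = None,
                       replicates: int = 20, seed: int = 0,
                       tau: float = 0.1) -> CommunityResult:
    """k-means module detection on per-gene standardized profiles.

    For each k in [k_min, k_max] the lowest-SSE replicate is kept; the
    replicate pool contains ``replicates`` random k-means++ starts plus
    one start that augments the best (k-1)-solution's centers with the
    point farthest from its center, which guarantees the kept SSE curve
    is non-increasing in k.  The returned assignment is at the k selected
    from the scree of that curve.
    """
    nodes = list(nodes)
    if k_max is None:
        k_max = min(10, len(nodes) - 1)
    if k_max < k_min:
        raise ValueError("k_max < k_min")
    if k_max >= len(nodes):
        raise ValueError("k_max must be below the number of nodes")
    sub = (matrix.to_log2() if not matrix.is_log2 else matrix).subset_genes(nodes)
    x = _zscore_rows(sub.values.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)

    sse_curve: dict[int, float] = {}
    labels_at_k: dict[int, np.ndarray] = {}
    prev_centers: np.ndarray | None = None
    for k in range(k_min, k_max + 1):
        best_inertia, best_labels, best_centers = np.inf, None, None
        inits: list = ["k-means++"] * replicates
        if prev_centers is not None:
            dists = ((x[:, None, :] - prev_centers[None, :, :]) ** 2).sum(axis=2)
            worst = int(np.argmax(dists.min(axis=1)))
            inits.append(np.vstack([prev_centers, x[worst]]))
        for init in inits:
            km = KMeans(n_clusters=k, init=init,
                        n_init=1, random_state=int(rng.integers(2 ** 31)))
            km.fit(x)
            if km.inertia_ < best_inertia:
                best_inertia = km.inertia_
                best_labels = km.labels_
                best_centers = km.cluster_centers_
        sse_curve[k] = float(best_inertia)
        labels_at_k[k] = best_labels
        prev_centers = best_centers

    k_sel = select_k_scree(sse_curve, tau=tau) if len(sse_curve) >= 2 else k_min
    assignment = pd.Series(labels_at_k[k_sel], index=nodes, name="module")
    return CommunityResult(assignment=assignment, sse_curve=sse_curve, k=k_sel)


def select_k_scree(sse_curve: Mapping[int, float], tau: float = 0.1) -> int:
    """Smallest k whose relative SSE improvement to k+1 falls below tau;
    falls back to the largest k when the curve never flattens."""
    ks = sorted(sse_curve)
    if len(ks) < 2:
        raise ValueError("scree selection needs at least 2 points")
    for k, k_next in zip(ks, ks[1:]):
        s = sse_curve[k]
        drop = 0.0 if s == 0 else (s - sse_curve[k_next]) / s
        if drop < tau:
            return k
    return ks[-1]


# ---------------------------------------------------------------------------
# node coordinates
# ---------------------------------------------------------------------------

def apcc(graph: nx.Graph) -> pd.Series:
    """Average Pearson correlation of each node with its neighbors: the
    mean weight of incident edges.  Isolated nodes are undefined and
    excluded (logged)."""
    vals = {}
    isolated = []
    for node in graph.nodes:
        weights = [d["weight"] for _, _, d in graph.edges(node, data=True)]
        if weights:
            vals[node] = float(np.mean(weights))
        else:
            isolated.append(node)
    if isolated:
        log.info("apcc: %d isolated node(s) excluded: %s",
                 len(isolated), isolated[:5])
    return pd.Series(vals, dtype=float)


def within_module_degree_z(graph: nx.Graph, modules: Mapping[str, int],
                           standardize: str = "within") -> pd.Series:
    """Within-module degree z-score Zg.

    k_i counts edges from node i into its own module; by default the
    z-score is taken over the nodes of that module (population sd;
    sd = 0 gives Zg = 0).  ``standardize="global"`` standardizes over all
    nodes instead.
    """
    if standardize not in ("within", "global"):
        raise ValueError("standardize must be 'within' or 'global'")
    k_in = {}
    for node in graph.nodes:
        if node not in modules:
            raise KeyError(f"node {node!r} has no module assignment")
        m = modules[node]
        k_in[node] = sum(1 for nb in graph.neighbors(node) if modules[nb] == m)
    ser = pd.Series(k_in, dtype=float)
    out = pd.Series(index=ser.index, dtype=float)
    if standardize == "global":
        sd = ser.std(ddof=0)
        out[:] = 0.0 if sd == 0 else (ser - ser.mean()) / sd
        return out
    module_ids = pd.Series({n: modules[n] for n in ser.index})
    for m in module_ids.unique():
        members = module_ids.index[module_ids == m]
        vals = ser.loc[members]
        sd = vals.std(ddof=0)
        out.loc[members] = 0.0 if sd == 0 else (vals - vals.mean()) / sd
    return out


def clusterphobic(graph: nx.Graph, modules: Mapping[str, int]) -> pd.Series:
    """Clusterphobic coefficient Kpi = 1 - (k_in / k_tot)^2, in [0, 1]:
    0 when all edges are internal to the node's module, 1 when all are
    external.  Degree-0 nodes are excluded."""
    vals = {}
    for node in graph.nodes:
        k_tot = graph.degree(node)
        if k_tot == 0:
            continue
        m = modules[node]
        k_in = sum(1 for nb in graph.neighbors(node) if modules[nb] == m)
        vals[node] = 1.0 - (k_in / k_tot) ** 2
    return pd.Series(vals, dtype=float)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CartographyThresholds:
    """Boundaries of the heat-cartography plane.

    Only the switch-defining boundaries (Zg 2.5, Kpi 0.8) and the hub
    threshold (Zg 5) are fixed by the procedure; the remaining R1-R7
    breakpoints follow the classic cartography convention and are
    configurable.
    """

    zg_hub: float = 5.0
    zg_region: float = 2.5          # separates rows R1-R4 from R5-R7
    kpi_switch: float = 0.8
    apcc_date_party: float = 0.5    # date below, party at/above
    nonhub_kpi_bounds: tuple[float, float] = (0.05, 0.62)  # R1|R2, R2|R3
    hub_kpi_bounds: tuple[float, float] = (0.30, 0.75)     # R5|R6, R6|R7


def classify_nodes(zg: pd.Series, kpi: pd.Series, apcc_values: pd.Series,
                   thresholds: CartographyThresholds = CartographyThresholds(),
                   ) -> pd.DataFrame:
    """Roles, cartography regions and switch calls from (Zg, Kpi, APCC).

    Only nodes with all three coordinates defined are classified.  The
    switch rule is strict: Zg < 2.5 AND Kpi > 0.8 AND APCC < 0, so a node
    sitting exactly on a boundary is not a switch.
    """
    t = thresholds
    nodes = zg.index.intersection(kpi.index).intersection(apcc_values.index)
    zg, kpi, ap = zg.loc[nodes], kpi.loc[nodes], apcc_values.loc[nodes]

    role = pd.Series(ROLE_PARTY, index=nodes, dtype=object)
    role[ap < t.apcc_date_party] = ROLE_DATE
    role[ap < 0] = ROLE_FIGHT_CLUB

    region = pd.Series(index=nodes, dtype=object)
    low = zg < t.zg_region
    b1, b2 = t.nonhub_kpi_bounds
    region[low & (kpi <= b1)] = "R1"
    region[low & (kpi > b1) & (kpi <= b2)] = "R2"
    region[low & (kpi > b2) & (kpi <= t.kpi_switch)] = "R3"
    region[low & (kpi > t.kpi_switch)] = "R4"
    h1, h2 = t.hub_kpi_bounds
    region[~low & (kpi <= h1)] = "R5"
    region[~low & (kpi > h1) & (kpi <= h2)] = "R6"
    region[~low & (kpi > h2)] = "R7"

    is_switch = (zg < t.zg_region) & (kpi > t.kpi_switch) & (ap < 0)
    return pd.DataFrame({
        "Zg": zg, "Kpi": kpi, "APCC": ap,
        "is_hub": zg > t.zg_hub,
        "role": role,
        "region": region,
        "is_switch": is_switch,
    })


def node_cartography(graph: nx.Graph, modules: Mapping[str, int],
                     thresholds: CartographyThresholds = CartographyThresholds(),
                     standardize: str = "within") -> pd.DataFrame:
    """Convenience composition: Zg, Kpi, APCC then classification, with
    the module id attached."""
    zg = within_module_degree_z(graph, modules, standardize=standardize)
    kpi = clusterphobic(graph, modules)
    ap = apcc(graph)
    carto = classify_nodes(zg, kpi, ap, thresholds)
    carto.insert(0, "module", pd.Series({n: modules[n] for n in carto.index}))
    return carto


# ---------------------------------------------------------------------------
# robustness
# ---------------------------------------------------------------------------

def average_shortest_path(graph: nx.Graph) -> float:
    """Unweighted average shortest path length of the largest connected
    component; 0 when fewer than 2 nodes remain connected."""
    if graph.number_of_nodes() == 0:
        return 0.0
    adj = nx.to_scipy_sparse_array(graph, weight=None, format="csr")
    _, labels = csgraph.connected_components(adj, directed=False)
    sizes = np.bincount(labels)
    comp = int(sizes.argmax())
    if sizes[comp] < 2:
        return 0.0
    idx = np.where(labels == comp)[0]
    dist = csgraph.shortest_path(adj[idx][:, idx], method="D",
                                 unweighted=True, directed=False)
    m = len(idx)
    return float(dist.sum() / (m * (m - 1)))


def robustness_curve(graph: nx.Graph, cartography: pd.DataFrame,
                     removal_fractions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
                     class_replicates: int = 20,
                     random_replicates: int = 100,
                     seed: int = 0) -> dict[str, pd.DataFrame]:
    """Targeted node-removal curves for each node class.

    For each class (date, party, fight-club, switch, random) nodes of the
    class are removed in random order (replicated) and the average
    shortest path of the largest remaining component is recorded on a
    grid of fractions of the class size.  Every class also carries a
    random baseline at the same removed-node counts (mean and sd over
    ``random_replicates`` draws from all nodes) so targeted removal can
    be compared against chance.  Empty classes are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    all_nodes = list(graph.nodes)
    classes: dict[str, list] = {
        ROLE_DATE: list(cartography.index[cartography["role"] == ROLE_DATE]),
        ROLE_PARTY: list(cartography.index[cartography["role"] == ROLE_PARTY]),
        ROLE_FIGHT_CLUB: list(cartography.index[cartography["role"] == ROLE_FIGHT_CLUB]),
        "switch": list(cartography.index[cartography["is_switch"]]),
        "random": all_nodes,
    }

    def _apl_after_removal(members: list, count: int, reps: int,
                           generator: np.random.Generator) -> np.ndarray:
        out = np.empty(reps)
        for r in range(reps):
            drop = generator.permutation(len(members))[:count]
            removed = {members[i] for i in drop}
            sub = graph.subgraph([n for n in all_nodes if n not in removed])
            out[r] = average_shortest_path(sub)
        return out

    random_cache: dict[int, tuple[float, float]] = {}

    def _random_baseline(count: int) -> tuple[float, float]:
        if count not in random_cache:
            apls = _apl_after_removal(all_nodes, count, random_replicates, rng)
            random_cache[count] = (float(apls.mean()), float(apls.std(ddof=0)))
        return random_cache[count]

    curves: dict[str, pd.DataFrame] = {}
    for name, members in classes.items():
        if not members:
            log.warning("robustness_curve: class %r is empty, curve omitted", name)
            continue
        rows = []
        for frac in removal_fractions:
            count = int(round(frac * len(members)))
            if count == 0:
                base = average_shortest_path(graph)
                apl_mean, apl_sd = base, 0.0
            else:
                reps = 1 if count == len(members) and name != "random" else class_replicates
                apls = _apl_after_removal(members, count, reps, rng)
                apl_mean, apl_sd = float(apls.mean()), float(apls.std(ddof=0))
            rand_mean, rand_sd = _random_baseline(count)
            rows.append({"fraction": frac, "n_removed": count,
                         "apl_mean": apl_mean, "apl_sd": apl_sd,
                         "rand_mean": rand_mean, "rand_sd": rand_sd})
        curves[name] = pd.DataFrame(rows)
    return curves


# ---------------------------------------------------------------------------
# end-to-end composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwimParams:
    """Tunables of the end-to-end switch-gene run (defaults are the
    procedure's standard cutoffs)."""

    fc_cutoff: float = 1.5
    alpha: float = 0.05
    r_threshold: float = 0.7
    k_min: int = 2
    k_max: int = 10
    kmeans_replicates: int = 20
    tau: float = 0.1
    thresholds: CartographyThresholds = CartographyThresholds()
    removal_fractions: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    class_replicates: int = 20
    random_replicates: int = 100
    compute_robustness: bool = True
    seed: int = 0


@dataclass
class SwimResult:
    de_table: pd.DataFrame
    filtered_genes: list[str]
    network: nx.Graph | None
    communities: CommunityResult | None
    cartography: pd.DataFrame | None
    switch_genes: list[str]
    robustness: dict[str, pd.DataFrame] | None
    heatmap: pd.DataFrame | None

    @property
    def empty(self) -> bool:
        return self.network is None


def _bicluster_order(values: pd.DataFrame) -> pd.DataFrame:
    """Order rows and columns by average-linkage hierarchical clustering
    on correlation distance (biclustering of the switch-gene submatrix)."""
    def _order(x: np.ndarray) -> np.ndarray:
        if len(x) < 3:
            return np.arange(len(x))
        d = pdist(x, metric="correlation")
        d = np.nan_to_num(d, nan=1.0)
        return leaves_list(_average_linkage(d))
    rows = _order(values.to_numpy(dtype=float))
    cols = _order(values.to_numpy(dtype=float).T)
    return values.iloc[rows, cols]


def run_swim(matrix: ExpressionMatrix, contrast: tuple[str, str],
             params: SwimParams = SwimParams()) -> SwimResult:
    """The full switch-gene pipeline for one two-group contrast.

    Composes the significance filter, correlation network, k-means
    communities, cartography coordinates, classification and (optionally)
    the robustness analysis; emits the switch-gene expression submatrix
    biclustered by correlation distance when at least two switch genes
    are found.
    """
    log_matrix = matrix.to_log2() if not matrix.is_log2 else matrix
    de = differential_expression(log_matrix, contrast[0], contrast[1])
    genes = swim_filter(de, fc_cutoff=params.fc_cutoff, alpha=params.alpha)
    if len(genes) < max(3, params.k_min + 1):
        log.warning("run_swim: only %d genes survive the filter; "
                    "returning an empty result", len(genes))
        return SwimResult(de, genes, None, None, None, [], None, None)

    graph = build_correlation_network(log_matrix, genes,
                                      r_threshold=params.r_threshold)
    nodes = list(graph.nodes)
    comm = kmeans_communities(log_matrix, nodes, k_min=params.k_min,
                              k_max=min(params.k_max, len(nodes) - 1),
                              replicates=params.kmeans_replicates,
                              seed=params.seed, tau=params.tau)
    modules = comm.assignment.to_dict()
    carto = node_cartography(graph, modules, params.thresholds)
    switches = sorted(carto.index[carto["is_switch"]])

    robustness = None
    if params.compute_robustness:
        robustness = robustness_curve(
            graph, carto, removal_fractions=params.removal_fractions,
            class_replicates=params.class_replicates,
            random_replicates=params.random_replicates, seed=params.seed)

    heatmap = None
    if len(switches) >= 2:
        heatmap = _bicluster_order(log_matrix.values.loc[switches])
    else:
        log.warning("run_swim: %d switch gene(s); heatmap stage skipped",
                    len(switches))
    return SwimResult(de, genes, graph, comm, carto, switches, robustness,
                      heatmap)
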