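# Methods

## Pipeline overview

Two branches share the differential-expression front end.

The **network branch** takes a genes × samples intensity matrix with a
two-group contrast, computes per-gene log2 fold change (difference of
log2 group means), Welch two-sample t p-values and Benjamini–Hochberg q,
keeps genes with |FC| ≥ 1.5 and q ≤ 0.05, and builds a signed Pearson
co-expression network over them: edge iff |r| ≥ 0.7 (configurable; a
density-targeted mode is provided), weight keeping the sign of r.
Communities are found by k-means on z-scored expression profiles; for
each k the lowest-SSE replicate of 20 is kept, and k is the smallest
value whose relative SSE improvement falls below τ = 0.1 (fallback: the
largest k scanned). Per node we compute the within-module degree z-score
Zg (population sd within the node's module; sd = 0 ⇒ Zg = 0), the
clusterphobic coefficient Kπ = 1 − (k_in/k_tot)², and APCC, the mean
weight of incident edges. Roles follow APCC (fight-club < 0 ≤ date < 0.5
≤ party), hubs have Zg > 5, and switch genes satisfy the strict rule
Zg < 2.5 ∧ Kπ > 0.8 ∧ APCC < 0 (region R4). Robustness removes the nodes
of each class in random order (20 replicates) and records the average
shortest path of the largest connected component on a grid of class
fractions, against a random baseline matched in removed-node count
(100 replicates, mean ± sd).

The **signature branch** preprocesses intensities the way rank-based
meta-analysis engines do: non-positive values floored to the dataset's
smallest positive value (zeros included, so the final log2 stays
defined), genes below the 20th percentile of gene-mean intensity
removed, log2 last. Signatures keep genes with p ≤ 0.05 and |FC| ≥ 1.2,
ranked by p (ties: larger |log2fc|, then gene id) and scored
ceil(100·(N − rank + 1)/N) — the rank enters only through rank/N, so the
score is platform-size invariant. Two signatures over a shared universe
are compared by scanning hypergeometric upper-tail tests over the decile
rank cutoffs of both signatures for the pooled concordant and discordant
direction hypotheses; the reported p is the minimum × (number of tests)
capped at 1, the sign is the winning hypothesis's. The winner is chosen
by a canonical key (smallest p, largest overlap, concordant first,
smaller cutoff pair), which makes the result independent of scan order
and exactly symmetric under swapping the signatures; direction-flipping
one signature swaps the two hypotheses' statistics, giving exact
antisymmetry of the sign at identical p. This is a reimplementation of
the published *description* of the rank-scan ("running Fisher")
comparison; the commercial engine's exact grid and correction are
unpublished, so numerical agreement with it is not expected.

Directional enrichment intersects each gene set with the measured
universe, tests only sets of size 10–500 by the same hypergeometric
upper tail, and corrects by BH across tested sets. Regulator ranking
filters TF→target edges by peak signal < 500 and regulatory potential
< 1 (strict), restricts targets to the query genes, and ranks TFs by
degree with betweenness centrality (computed on the filtered bipartite
graph) as tie-break — degree first because no combination rule is
established.

## Synthetic data: what it emulates, and what it does not

The generator emulates log-scale microarray intensities with activity
group structure. Values are built on the log2 scale — per-gene baseline
~ U(5, 9), latent-factor signal, Gaussian noise, planted group-mean
shifts — then exponentiated, so intensities are strictly positive and a
planted log2FC is recovered exactly at zero noise.

**Factor model.** A gene in module m is `a·f_m + σ·ε` with
`a = σ·sqrt(r/(1−r))`, so the expected within-module pairwise
correlation is exactly the configured `r = a²/(a²+σ²)` (default 0.8;
the tests check the empirical mean lands within ±0.1 at module size 30,
n = 60). Module factors are equicorrelated (`factor_corr`, default 0.3),
modelling related pathway activity. This correlation is load-bearing: a
planted switch gene carries equal negative loadings (−0.8a) on each of
its foreign factors and a near-zero loading (+0.083a) on its own module,
and its correlation with a foreign-module gene scales with b(1+ρ). With
independent factors (ρ = 0) a two-factor loader is capped at
`r_within/√2 ≈ 0.57`, below any realistic edge threshold, and the
planted "switch" would dangle off a single module instead of bridging
several — defeating its definition as an inter-module connector.

**Planted differential expression.** The recovery study condition
(`switch_recovery_config`) shifts every module gene by +1.5 log2FC in
the highest activity group and every switch gene by −1.5. Shifts share
the group indicator, so genes shifted in the same direction gain
correlation (~0.29 cross-module at the defaults, safely under the 0.7
edge threshold) and a switch's opposite shift deepens its
anti-correlation with the modules it bridges. Module shifts are kept
uniform in sign because one switch shift can only oppose module shifts
that agree; the default noise (σ = 0.5, giving factor variance 1.25) is
chosen so the factor signal, not the shift, dominates the correlation
structure.

**Signature pairs** share exactly `round(overlap·n_sig)` genes with
exactly `round(concordance·shared)` concordant directions; p-values
(log-uniform on [1e−8, 0.05]) and fold changes (|log2FC| uniform on
[log2 1.2, 2.5]) are sampled so every signature gene passes the
significance filter. Gene sets are uniform random draws plus one planted
set given verbatim; TF edges contain one planted regulator targeting
every query gene with filter-passing scores and background regulators
whose scores straddle the filters.

Every generator is a pure function of its seed.

What the generator does **not** emulate: probe-level effects, batch and
platform artifacts, heavy-tailed or intensity-dependent noise,
covariates, and realistic network topology at scale (the planted
networks are three dense modules plus connectors, not a genome-wide
scale-free graph). Passing recovery tests therefore demonstrates the
correctness of the machinery on data satisfying the model's assumptions,
not performance on real arrays.

## Numerical choices and degenerate inputs

- Welch t with zero variance in both groups (or any undefined result)
  gets p = 1; groups need ≥ 2 samples.
- Constant genes cannot be correlated and are dropped from the network
  with a warning; isolated nodes are kept but excluded from APCC and
  classification. Fewer than about k_min + 1 filter survivors short-
  circuits to an empty result.
- Ranking ties break deterministically (p, then |log2fc| descending,
  then gene id); majority-direction ties in the meta-ranking break by
  summed score, then "up".
- The k-means replicate pool at each k adds one start that augments the
  best (k−1) centers with the farthest point, guaranteeing the kept SSE
  curve is non-increasing (Lloyd's algorithm only improves its
  initialization), so the scree rule is well defined.
- The hypergeometric tail is evaluated with canonically ordered margins
  so swapped signatures give bit-identical p-values.
- Boundary conventions are strict: Zg = 2.5 or Kπ = 0.8 is not a switch;
  size-9 and size-501 sets are not tested; signal = 500 or potential = 1
  edges are excluded.
- The switch-gene heatmap orders rows and columns by average-linkage
  hierarchical clustering on correlation distance; it is skipped with a
  warning below two switch genes.
- Average shortest paths are computed by BFS on the sparse adjacency
  (scipy.sparse.csgraph) over the largest connected component; fewer
  than two connected nodes give 0.

## Design choices where the procedure was open

- The DE statistic is unspecified upstream of the network filter; Welch
  t on log2 intensities was chosen as the standard two-group microarray
  contrast robust to unequal variances.
- The "20th percentile of combined signal intensities" is interpreted
  per gene mean with linear-interpolation percentiles (the per-value
  alternative would remove parts of genes, which the downstream matrix
  cannot represent).
- Zg standardizes within each module (the classic cartography
  convention); a `standardize="global"` option is provided.
- The R1–R7 breakpoints beyond Zg = 2.5 and Kπ = 0.8 follow the classic
  cartography boundaries and are configurable; only R4 affects switch
  calls.
- The signature universe for pair comparison is the intersection of the
  platforms' measured genes, preventing platform-size bias.
- Problem sizes in the test and acceptance runs (100 genes, 60 samples,
  20 seeds; 2000-gene universes, 100 signature pairs) are the package's
  default study conditions: large enough that the factor-model
  asymptotics hold, small enough to iterate quickly.

## Known limitations

- The rank-scan comparison is a faithful implementation of the published
  description, not a bit-compatible clone of the proprietary engine.
- k-means with scree selection can refine tight clusters further than
  the planted count on noisy data; switch classification is robust to
  this (the detected module of a switch only enters through k_in), but
  module identities themselves should be read as one plausible
  partition.
- The robustness baseline treats all nodes as exchangeable under random
  removal; class-size-matched randomization within roles is not
  implemented.
- GEO parsing covers the series-matrix dialect only (no SOFT, no CEL
  normalization); probe→gene collapsing is available as max-mean but no
  other rule.
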