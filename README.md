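# netswitch

Switch-gene detection in gene co-expression networks and rank-based
directional correlation of differential-expression signatures, with a
synthetic-data generator that plants known ground truth so the whole
analysis can run and validate without any external downloads.

## The scientific problem

Transcriptomic studies of brain tissue from aged, cognitively intact
people who engaged in different levels of physical activity — and from
patients with neurodegenerative diseases (Alzheimer's, Parkinson's,
Huntington's, frontotemporal dementia) — raise two computational
questions this package answers:

1. **Which genes sit at the hinge of drastic transcriptional change?**
   In a signed Pearson co-expression network built over differentially
   expressed genes, *switch genes* are nodes that are not hubs within
   their own community (within-module degree z-score `Zg < 2.5`), connect
   mostly outside their community (clusterphobic coefficient
   `Kπ = 1 − (k_in/k_tot)² > 0.8`), and are on average *anti*-correlated
   with their interaction partners (average Pearson correlation
   coefficient, `APCC < 0`). They are a subset of the "fight-club" hubs
   (negative APCC) and occupy region R4 of the heat-cartography plane
   spanned by (`Kπ`, `Zg`). Communities come from k-means on standardized
   expression profiles with the cluster count chosen from the scree of
   the SSE curve; `Zg > 5` marks hubs; robustness is probed by targeted
   node removal while tracking the average shortest path of the largest
   connected component.

2. **Do two differential signatures move together or in opposition?**
   Each two-group contrast yields a signature: genes with `p ≤ 0.05` and
   `|FC| ≥ 1.2`, ranked by significance and given a platform-size-free
   score from 100 (top) down to 1. Two signatures over a shared measured
   universe are compared by scanning one-sided Fisher exact (hypergeometric
   upper-tail) tests over rank cutoffs of both signatures — separately for
   the pooled concordant (up-up ∪ down-down) and discordant
   (up-down ∪ down-up) hypotheses — taking the minimum p with a
   Bonferroni correction over all tests. The winning hypothesis gives the
   correlation sign; `−log10 p` is the reported effect scale. Discordant
   gene partitions feed hypergeometric gene-set enrichment (set sizes
   10–500, BH-corrected) and regulator ranking over a TF→target edge list
   (degree, then betweenness centrality, after peak-signal < 500 and
   regulatory-potential < 1 edge filters).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data with planted truth:

```sh
python analysis/01_simulate.py --seed 1
python analysis/03_switch_genes.py --seed 1
python analysis/04_signature_correlation.py --seed 1
```

prints (abridged):

```
simulated 100 genes x 60 samples (low, moderate, high; seed 1)
planted: 3 modules x 30 genes, 5 switch genes, 95 DE genes at |log2FC| = 1.5

seed 1: 5 switch genes detected (['SW00', 'SW01', 'SW02', 'SW03', 'SW04']), network k = 4
  switch-removal curve leaves the random 95% band at 4/6 grid points
recovery over 5 seeds: precision 1.00, recall 1.00

high_pa_vs_disease: sign negative (opposing), -log10 p = 41.6, 100 shared genes (90 discordant / 10 concordant)
low_pa_vs_disease: sign positive (same direction), -log10 p = 41.6, 100 shared genes (10 discordant / 90 concordant)
```

All five planted switch genes are recovered exactly; removing them
disconnects the network's communities, which is why the targeted-removal
curve leaves the random band. Signature pairs planted with mostly
opposite fold-change directions are called negatively correlated and
mostly same-direction pairs positively — the qualitative pattern expected
between activity and disease signatures.

The same pipeline runs from a config file:

```sh
netswitch all -c configs/synth.yaml --out-dir results/synth_run
```

writing the differential tables, cartography coordinates, switch list,
biclustered switch-gene heatmap, robustness curves, correlation panel,
enrichment tables, TF ranking and a manifest (config hash, seed,
library versions). `netswitch simulate|de|switch|correlate|enrich` run
the stages individually and resume from each other's outputs. Real data
can be supplied as a GEO series-matrix file or plain TSV through the
config's `input` section.

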