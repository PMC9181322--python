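# Bundled synthetic end-to-end configuration.
# Thresholds are the pipeline defaults (FC 1.5 / q 0.05 for the network
# branch, p 0.05 / FC 1.2 for signatures, |r| 0.7, Zg 2.5, Kpi 0.8,
# set sizes 10-500); they are restated in code, not here.
seed: 1
out_dir: results/synth_run

synthetic:
  n_genes: 100
  n_samples_per_group: 20
  groups: [low, moderate, high]
  n_modules: 3
  module_size: 30
  within_module_r: 0.8
  n_switch: 5
  switch_foreign_modules: 2
  noise_sd: 0.5
  plant_de: true
  de_log2fc: 1.5

contrast: [low, high]

signatures:
  n_universe: 2000
  n_sig: 200
  pairs:
    - {name: disease_discordant, overlap_fraction: 0.5, concordance: 0.1}
    - {name: disease_concordant, overlap_fraction: 0.5, concordance: 0.9}

enrichment:
  n_sets: 30
  size_range: [10, 200]

tf:
  n_tfs: 10
  targets_per_tf: 15
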