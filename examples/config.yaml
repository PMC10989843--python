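# full study-scale configuration (defaults shown explicitly)
seed: 7
simulate:
  n_blocks: 4
  n_months: 12
  n_otus: 600
  n_modules: 5
  module_size: 20
  assoc_strength: 0.95
  depth: 17700
# to analyze real tables instead of simulating:
# inputs:
#   otu: path/to/otu.tsv
#   meta: path/to/meta.tsv
#   env: path/to/env.tsv
rarefaction_depth: 17700
beta:
  metric: bray_curtis
  dispersion_metric: sorensen
  n_perm: 999
network:
  prevalence_fraction: 0.75
  transform: log10_pseudocount
  seasonal_s_t: 0.890
  global_s_t: 0.680
topology:
  n_nulls: 30
robustness:
  fraction: 0.5
  n_hubs: 5
  n_reps: 100
nst:
  grouping: treatment_season
  metric: jaccard
  n_rand: 200
  n_perm: 1000
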