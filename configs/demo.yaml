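# Demo configuration: synthetic world at the study's scale
# (11 cell lines x 3 replicates), full pipeline, default thresholds.
outdir: demo_run
seed: 7
simulate:
  n_proteins: 2000
alpha: 0.01
min_detect: 0.5
log10: true
n_pairs: 1000
feature_bins: 5
mutation_bins: 5
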