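# Demo pipeline configuration: small synthetic cohort, reduced-draw fit.
#   gcjoint run examples/config.yaml
seed: 5
outdir: gcjoint_out
sim:
  n_females: 60
  obs_window_years: 10.0
  n_groups: 3
mcmc:
  chains: 2
  iterations: 1000
  warmup: 500
assoc_mode: auc
assoc_alpha: 0.115
predict:
  percentiles: [90, 10]
  t0: 12.0
  grid_max: 26.0
  grid_step: 0.25
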