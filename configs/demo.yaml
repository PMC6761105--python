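# Demo pipeline configuration: two small synthetic cohorts with three
# planted signal metabolites; completes in well under a minute.
master_seed: 1
output_dir: runs/demo
cohorts:
  train:
    simulate:
      preset: satin_like
      n_subjects: 60
      n_metabolites: 25
      n_high_missing: 3
      n_signal: 3
      effect_sizes: [1.2, -1.0, 0.9]
      block_structure: [[6, 0.6], [5, 0.4]]
      high_missing_rate: 0.34
  validation:
    simulate:
      preset: glyndiet_like
      n_subjects: 30
      n_metabolites: 25
      n_high_missing: 3
      n_signal: 3
      effect_sizes: [1.2, -1.0, 0.9]
      block_structure: [[6, 0.6], [5, 0.4]]
      high_missing_rate: 0.34
followup:
  coef_weight: 0.05
  coef_baseline: -0.4
  coef_latent: 0.3
  noise_sd: 0.5
preprocess:
  threshold: 0.20
  rf_trees: 20
  max_iter: 3
enet:
  alpha: 0.5
  n_folds: 10
  n_lambda: 50
  lambda_min_ratio: 0.001
  cv_criterion: mse
stability:
  n_runs: 20
validation:
  mode: refit
sensitivity:
  exclude: [met_glucose]
loo:
  enabled: true
longitudinal:
  enabled: true
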