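# Example configuration for `episcope run --config pipeline.yaml --outdir out/`.
# Exactly one of `synth:` (simulate a cohort) or `inputs:` (paths to existing
# files) must be present; every field of SynthConfig/ForestConfig can be set.
seed: 7
synth:
  n_patients: 34
  n_survivors: 12
  n_tr: 14
  n_probes: 5000
  n_prognostic: 10
  n_responsive: 200
# inputs:
#   t0: data/beta_t0.tsv
#   t2: data/beta_t2.tsv
#   tr: data/beta_tr.tsv
#   manifest: data/manifest.csv
#   sheet: data/sample_sheet.csv
wilcoxon: auto          # exact-when-feasible; "approx" forces the normal branch
p_threshold: 0.8
alphas: [0.0, 0.00001, 0.05, 0.1, 0.2, 0.25]
classify_alphas: [0.1]  # one classifier report (and KM analysis) per alpha
standardize: true
cv_folds: 0             # >1 adds the cross-validated MSE tuning curve
episave: true           # also fit the SAVE-score fusion variant
forest:
  n_trees: 500
  seed: 0
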