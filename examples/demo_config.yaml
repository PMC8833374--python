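# Demo pipeline configuration for `stpscore run-all`.
# Simulates a small CD4+ T-cell style cohort, runs QC, calibrates frozen
# pathway models, scores the cohort, derives healthy-blood normal thresholds,
# classifies patient blood samples, compares Notch activity between patient
# and healthy blood, and matches tumour-infiltrate profiles to reference
# cell states.
seed: 17
out_dir: scratch/demo
simulate:
  n_replicates: 4
  n_patients: 6
  n_healthy: 4
  n_background_genes: 40
  n_genes_per_pathway: 12
  n_down_per_pathway: 3
  effect_size: 2.0
  noise_sd: 0.5
  qc_planted_failures: 2
  calib_n_per_class: 15
compare:
  pathway: Notch
  group_a: patient_blood
  group_b: healthy_blood
  alternative: two_sided
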