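# Full pipeline on a seeded synthetic cohort.
# For a real cohort replace `simulate` with expression/clinical/seg/maf paths.
seed: 7
outdir: out/
simulate:
  n_samples: 300
cluster:
  k_min: 1
  k_max: 6
  n_init: 4
deg:
  alpha: 0.05
  min_abs_log2fc: 1.0
lasso:
  n_folds: 5
  n_lambda: 50
horizons: [365, 730, 1095]
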