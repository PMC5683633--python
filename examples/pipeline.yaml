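# Full-pipeline configuration on a simulated cohort.
# For real data, replace `simulate: true` with:
#   counts_path: path/to/counts.tsv
#   samples_path: path/to/samples.tsv
simulate: true
sim:
  n_features: 159
  surv_spec:
    feature_coefs: {10: 1.0, 20: -0.8}
    baseline_hazard: 0.1
    censoring_rate: 0.1
    horizon: 5.3
comparisons: [DLBCL, HL]
alpha: 0.05
de_transform: weighted_logcpm
n_iter: 1000
train_fraction: 0.5
panel_size: 80
inclusion_n_iter: 200
survival_n_resamples: 20
survival_n_perm: 100
seed: 7
out_dir: run
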