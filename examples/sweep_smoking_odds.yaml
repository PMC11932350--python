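# One-factor sweep over the smoking odds ratio at 1 Gy, all other
# parameters at the default mechanism. Run with:
#   radconfound sweep --config examples/sweep_smoking_odds.yaml --reps 200
cohort_size: 80000
follow_up: 60.0
n_reps: 1000
seed: 0
dose_model: {geometric_mean: 0.2623, geometric_sd: 2.223, cap: 1.0}
smoking_model: {baseline_prob: 0.3, or_at_1gy: 32.0}
risk_model: {beta_r: 0.26236426, beta_s: 0.47000363, beta_u: 0.0}
n_dose_categories: 10
grid:
  smoking_model.or_at_1gy: [0.1, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
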