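# Default all-synthetic pipeline run: a 56-site x 3-replicate survey
# with the pH regime switch at 6.2, 21 paired contrasts (11/6/4 per
# effect type) and a 200-feature indicator table with 10 planted
# indicators per group.
seed: 0
survey:
  generate:
    n_sites: 56
    reps_per_site: 3
    ph_break: 6.2
    noise_sd: 0.2
contrasts:
  generate:
    n_pairs_per_type: [11, 6, 4]
    noise_sd: 0.2
# five samples per group: with three, exhaustive enumeration over the
# C(6,3)=20 label assignments caps the smallest attainable p at 0.1
features:
  generate:
    n_features: 200
    n_samples_per_group: 5
    n_planted_indicators: 10
threshold:
  window_width: 1.4
  step: 0.1
  min_points_per_window: 10
  drop_fraction: 0.5
models:
  criterion: aicc
indval:
  n_permutations: 1000
  statistic: max
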