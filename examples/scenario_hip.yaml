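# Study-scale scenario: gluteofemoral-fat (hip circumference) instruments
# against log adiponectin.  75 instruments explaining ~2.0% of exposure
# variance; causal effect +0.17 SD log adiponectin per SD hip circumference.
k_snps: 75
beta_true: 0.17
n_exposure: 210088
n_outcome: 29347
maf_range: [0.05, 0.5]
gamma_sd: 0.027
exposure_correlation: 0.5
seed: 2
noise_free: false
pleiotropy:
  fraction_invalid: 0.0
  mean: 0.0
  sd: 0.0
  directional: false
  inside_violation: false
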