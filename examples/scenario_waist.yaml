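# Study-scale scenario: abdominal-fat (waist circumference) instruments
# against log adiponectin.  56 instruments explaining ~1.2% of exposure
# variance, exposure GWAS n = 210 088, outcome GWAS n = 29 347, causal
# effect -0.27 SD log adiponectin per SD waist circumference.
k_snps: 56
beta_true: -0.27
n_exposure: 210088
n_outcome: 29347
maf_range: [0.05, 0.5]
gamma_sd: 0.024
exposure_correlation: 0.5
seed: 1
noise_free: false
pleiotropy:
  fraction_invalid: 0.0
  mean: 0.0
  sd: 0.0
  directional: false
  inside_violation: false
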