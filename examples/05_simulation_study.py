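"""Repeated-simulation study: estimator calibration at the study scale.

Runs 300 replicates of the waist-scale scenario (56 instruments,
beta = -0.27, consortium sample sizes) and a null scenario, reporting
bias, empirical vs estimated SE, 95% CI coverage and rejection rate per
method.  Coverage should sit near 95% and the null rejection rate near 5%.
"""

from adipomr import SimulationConfig, run_simulation_study
from adipomr.simulate import PAPER_WAIST_SCENARIO

cols = ["method", "bias", "empirical_se", "mean_se", "coverage", "rejection_rate"]

print("waist-scale scenario (truth -0.27), 300 replicates:")
summary = run_simulation_study(PAPER_WAIST_SCENARIO, n_reps=300, seed=1,
                               methods=("ivw", "ivw_re", "egger"))
print(summary[cols].to_string(index=False, float_format="%.4f"))

print("\nnull scenario (truth 0), 300 replicates:")
null = run_simulation_study(SimulationConfig(k_snps=56, beta_true=0.0),
                            n_reps=300, seed=2, methods=("ivw",))
print(null[cols].to_string(index=False, float_format="%.4f"))
print("\nrejection_rate in the null block is the empirical type-I error "
      "(nominal 0.05).")
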