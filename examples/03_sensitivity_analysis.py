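"""Sensitivity analysis when some instruments are invalid.

Generates a scenario in which 30% of SNPs carry directional pleiotropy
(direct effects on adiponectin not mediated by girth), then runs the
two-stage sensitivity workflow: stage one quantifies heterogeneity
(Cochran's Q, I2 with CI) and funnel asymmetry (Egger intercept test);
stage two compares the naive IVW estimate with the penalized weighted
median, MR-Egger, and the post-removal IVW (variants with Q contribution
above 3.84 dropped).
"""

from adipomr import (
    BootstrapConfig,
    PleiotropyConfig,
    SimulationConfig,
    cochran_q,
    egger_asymmetry_test,
    ivw,
    mr_egger,
    remove_heterogeneous_and_reestimate,
    significant_subset,
    simulate_harmonized,
    weighted_median,
)

config = SimulationConfig(
    k_snps=75, beta_true=-0.27, gamma_sd=0.08, seed=5,
    pleiotropy=PleiotropyConfig(fraction_invalid=0.3, mean=0.05, sd=0.01,
                                directional=True),
)
hset = significant_subset(simulate_harmonized(config)[0])
print(f"{hset.k} genome-wide significant instruments; "
      f"truth -0.27 with 30% pleiotropic SNPs (mean direct effect +0.05)\n")

het = cochran_q(hset)
print(f"Cochran's Q = {het.Q:.1f} on {het.df} df (p = {het.p_het:.2g}); "
      f"I2 = {het.i2:.0f}% (95% CI {het.i2_ci_low:.0f}, {het.i2_ci_high:.0f})")
asym = egger_asymmetry_test(hset)
print(f"funnel asymmetry: Egger intercept {asym.egger_intercept:+.4f}, "
      f"p = {asym.p_asym:.3g}")
print(f"{len(het.flagged)} variants flagged (per-SNP Q > 3.84)\n")

boot = BootstrapConfig(n_boot=1000, seed=1)
naive = ivw(hset)
slope, intercept = mr_egger(hset, boot=boot)
pwm = weighted_median(hset, penalized=True, boot=boot)
_, post_removal, _ = remove_heterogeneous_and_reestimate(hset)
for label, e in [("naive IVW", naive), ("MR-Egger slope", slope),
                 ("penalized weighted median", pwm),
                 ("IVW after removing flagged", post_removal)]:
    print(f"{label:28s} beta = {e.beta:+.3f} [{e.ci_low:+.3f}, {e.ci_high:+.3f}]")
print("\nThe naive IVW is pulled toward zero by the positive pleiotropy. "
      "The penalized weighted median and the post-removal IVW move back "
      "toward the truth of -0.27; MR-Egger pays for its weaker assumptions "
      "with a CI wide enough to cover the truth.")
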