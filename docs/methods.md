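# Methods

This note records the statistical models implemented in `adipomr`, the
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical conventions that matter for
reproducing results.

## Two-sample summary-data MR model

For SNP j, let γⱼ be its effect on the standardized exposure (waist or hip
circumference, BMI-adjusted) estimated with standard error σ_γⱼ in the
exposure GWAS, and Γⱼ its effect on standardized log adiponectin with
standard error σ_Γⱼ in an independent (non-overlapping) outcome GWAS. Under
the instrumental-variable assumptions, Γⱼ = β·γⱼ for all valid instruments,
and β is the causal effect in SD of log adiponectin per SD of exposure.

- **Wald ratio**: β̂ⱼ = Γ̂ⱼ/γ̂ⱼ with first-order SE σ_Γⱼ/|γ̂ⱼ|. The
  first-order SE ignores the uncertainty in γ̂ⱼ and understates the ratio's
  sampling SD for weak instruments (checked against a 10⁵-draw simulation
  and the second-order expansion in the tests).
- **IVW**: precision-weighted combination of Wald ratios, algebraically the
  weighted least-squares slope of Γ̂ on γ̂ through the origin with weights
  σ_Γⱼ⁻². The default SE is fixed-effect; `multiplicative_random` inflates
  it by max(1, √(Q/(k−1))), never deflating below the fixed-effect value.
  Fixed-effect is the default because it is the baseline method the
  analysis plan names; the multiplicative variant exists because real girth
  instruments are substantially heterogeneous (I² ≈ 46–72%).
- **Multivariable IVW**: origin-constrained WLS of Γ̂ on (γ̂, γ̂₂) jointly,
  with per-coefficient SEs from the inverse weighted normal-equations
  matrix; this yields mutually adjusted causal effects for two correlated
  exposures (waist adjusted for hip and vice versa). The default instrument
  set for the multivariable model is the union of both exposures'
  trait-specific sets. An exactly-zero second-exposure column is treated as
  a degenerate orthogonal case (exposure-1 estimate reduces to univariable
  IVW; exposure-2 gets β = 0 with infinite SE) rather than a rank error.
- **MR-Egger**: WLS of Γ̂ on γ̂ with an unconstrained intercept after
  orienting every SNP to γ̂ⱼ > 0 (the regression is not
  orientation-invariant; orientation to the exposure-raising allele is the
  method's convention). The intercept estimates average directional
  pleiotropy; the slope is consistent when instrument strength is
  independent of the direct effects (InSIDE). Analytic SEs use a
  multiplicative overdispersion factor floored at 1, with t(k−2) p-values;
  bootstrap CIs (below) are used when requested.
- **Weighted median**: per-SNP ratios ordered by value with weights
  wⱼ = γ̂ⱼ²/σ_Γⱼ² (inverse first-order ratio variance); the estimate is the
  linear interpolation of the ratio at normalized cumulative weight 0.5,
  using midpoint positions sⱼ = (Σᵢ≤ⱼwᵢ − wⱼ/2)/Σw. Penalization computes
  each SNP's Cochran-Q contribution against the unpenalized weighted-median
  estimate, converts it to an upper-tail χ²₁ probability qⱼ, and multiplies
  the weight by min(1, 20·qⱼ); the constant 20 is the penalized estimator's
  published default and is configurable.
- **Reverse MR**: the identical IVW computation with adiponectin
  instruments (e.g. the four ADIPOQ-region SNPs) as exposure and girth as
  outcome; only the labelling differs.

**Bootstrap**: SNP-level resampling with replacement, percentile 95% CIs,
default 1000 draws, seeded. P-values for bootstrap-based estimates use the
normal approximation with the bootstrap SD (floored at 10⁻¹² for degenerate
resamples). The percentile interval is widened, if necessary, to bracket
the point estimate. With homogeneous data the bootstrap CI width agrees
with the analytic width (tested at 2000 draws).

## Harmonization rules

Outcome (and second-exposure) records are re-expressed per copy of the
exposure's effect allele. Swapped alleles negate the beta and complement
the EAF; strand flips (A↔T, C↔G) are resolved before comparison. For
palindromic SNPs (A/T, G/C) the allele labels carry no orientation
information — each allele is the strand-image of the other — so orientation
comes from EAF agreement alone: both EAFs must lie outside
[0.5−w, 0.5+w] (default w = 0.08); same side of 0.5 keeps the beta,
opposite sides flip it; otherwise the SNP is dropped ("ambiguous
palindrome"), as is any palindrome missing an EAF. Every shared SNP is
either retained or logged with a drop reason, and all estimators are
invariant to arbitrary per-record allele re-labelling of the raw inputs
(property-tested).

## Instrument selection

Genome-wide filtering keeps p < 5×10⁻⁸ (strict inequality). LD pruning is
greedy clumping: repeatedly keep the smallest-p unprocessed SNP (ties
broken lexically by id) and remove candidates with r² ≥ 0.05 against it;
LD is supplied as a pairs file from an external reference, never computed.
Variants appearing in both exposures' sets are excluded from both.
Variance explained uses R² = Σ 2·EAF(1−EAF)·β² on the standardized-trait
scale; power is the asymptotic two-sided normal approximation with
non-centrality |β|·√(n·R²), which matches the IVW test's empirical
rejection rate within Monte-Carlo error at the study scale (tested at 2000
replicates).

`significant_subset` applies the genome-wide threshold directly to a
harmonized set. Simulation studies of orientation-sensitive estimators
(MR-Egger, weighted median) must include this step: unselected synthetic
instruments contain near-null γ's whose estimated sign is wrong, and
misoriented points collapse the Egger slope toward zero. Real instrument
sets cannot contain such SNPs, so selection is part of the study
conditions, not an optional filter.

## Heterogeneity and asymmetry diagnostics

Cochran's Q sums wⱼ(β̂ⱼ − β̂_IVW)² with wⱼ = γ̂ⱼ²/σ_Γⱼ² against the
full-set fixed-effect IVW estimate (a leave-one-out reference is available
behind a flag); I² = max(0, (Q−df)/Q)·100 with a test-based 95% CI from the
log-H method (SE of ln H from Q and df; for df = 1 with Q ≤ df+1, where the
null-side formula is undefined, the Q-branch formula is evaluated at the
branch boundary). Per-SNP contributions above the χ²₁ 95th percentile
(3.84) are flagged. Funnel asymmetry is the MR-Egger intercept test on the
oriented data, with funnel coordinates (1/se(β̂ⱼ), β̂ⱼ). The removal
sensitivity analysis is a single pass — compute Q, drop flagged SNPs,
re-run IVW once; iterating the pass can flag further SNPs and is
deliberately not done.

## Fractional-polynomial cohort arm

Outcome and depot values are standardized within sex (SD-per-SD
coefficients). FP2 models evaluate all 36 power pairs from
{−2, −1, −0.5, 0, 0.5, 1, 2, 3} on the raw positive depot scale, with
x⁰ ≡ ln x and repeated powers (p, p) → (xᵖ, xᵖ·ln x); transformed columns
are centred/scaled for conditioning (the Gaussian likelihood is
unchanged). Nonpositive depot values trigger a shift by half the smallest
positive value (error if any value remains nonpositive). The
best-fitting FP2 is compared with the linear model by a likelihood-ratio
test on 3 df (two power choices plus one coefficient), Gaussian OLS
deviance; the per-test Bonferroni threshold for the eight sex-by-depot
models is 0.05/8 = 0.00625. The 3-df reference makes the selected-model
test approximately sized (its empirical size at n ≈ 350 per sex sits near
the low end of the 5% Monte-Carlo band).

## Synthetic-data generators

`simulate_two_sample` draws MAFⱼ ~ U(0.05, 0.5), γⱼ ~ N(0, σ_γ²)
(bivariate with correlation 0.5 when a second exposure is configured),
direct effects αⱼ for a configurable invalid fraction, and
Γⱼ = β·γⱼ (+ β₂·γ₂ⱼ) + αⱼ. Observed estimates add independent noise per
sample with se = 1/√(2·MAF(1−MAF)·n) — the standardized-trait
approximation, so SEs scale as n^(−1/2) (tested). Alleles are assigned at
random including palindromic pairs, and the outcome/second-exposure records
are randomly re-expressed on the opposite allele or strand so harmonization
is genuinely exercised. Directional pleiotropy is sign-coupled to γ
(αⱼ → αⱼ·sign(γⱼ)): "directional" is defined relative to the
exposure-raising allele, which is what the oriented Egger intercept
estimates; without the coupling, symmetric γ's would average the bias away
and the scenario would not represent directional pleiotropy at all. The
InSIDE-violation option instead couples α to |γ|.

Scenario defaults are the study scale: 56 waist-like instruments with
σ_γ = 0.024 (≈1.2% variance explained) or 75 hip-like instruments with
σ_γ = 0.027 (≈2.0%), exposure n = 210 088, outcome n = 29 347, causal
effects −0.27 and +0.17, no sample overlap. Presets
`PAPER_WAIST_SCENARIO`/`PAPER_HIP_SCENARIO` and the YAML files in
`examples/` carry these values.

`simulate_cohort` draws four correlated fat depots on raw scales matched to
published adult-cohort means/SDs (e.g. visceral 6.8 ± 1.9 cm in men,
4.9 ± 1.6 in women), with visceral–subcutaneous correlations ≈ 0.4 and
≈ 0.6 among subcutaneous depots, plus ancestry and lifestyle covariates.
Standardized log adiponectin is generated from adjusted depot effects
(−0.24 visceral, −0.07 deep subcutaneous, −0.20 superficial subcutaneous,
+0.13 gluteofemoral, SD per SD) so that the unadjusted gluteofemoral
association is negative while the adjusted one is positive — the
confounding-by-correlated-depot sign flip. The optional U-shaped
dose-response adds s·(z² − 1) to the predictor; the default strength 0.1
produces a likelihood-ratio statistic near 30 at n ≈ 1300 per sex,
curvature of the order reported in adult cohorts. Residual SD defaults to
the value giving unit outcome variance.

What the generators do **not** emulate: LD between instruments (the LD
input is exercised with explicit pairs files instead), genomic positions,
winner's-curse from discovery-and-use of the same sample, sample overlap
between exposure and outcome GWAS, EAF estimation error between studies,
non-Gaussian effect-size distributions, and missing data in the cohort
(complete cases by construction). Passing tests therefore demonstrate
correctness of the estimators and pipeline under the stated model, not
robustness to these additional features of real consortium data.

## Numerical choices and known limitations

- Finite-sample IVW carries a deterministic weak-instrument attenuation
  ≈ σ_γ²/(σ_γ² + se_γ²) (≈0.98 at the study scale, i.e. mean estimate
  −0.265 for a truth of −0.27). Recovery tests budget for this analytic
  term plus 3 Monte-Carlo SEs rather than pretending the estimator is
  exactly unbiased.
- Sizes used in the shipped simulations: 1000 replicates for
  recovery/coverage, 2000 for type-I error, 500 for robustness orderings,
  200 for the FP size/power study — chosen to give Monte-Carlo SEs well
  inside the asserted bands.
- Collinearity in the multivariable model is declared when the weighted
  normal-equations matrix has condition number above 10¹².
- P-value conventions: normal-theory for Wald/IVW/MV-IVW; t(k−2) for
  analytic Egger; bootstrap-SD normal approximation for bootstrap-based
  estimates. Simulated p-values are clipped to ≥ 10⁻³⁰⁰.
- The weighted median requires k ≥ 3 and >50% valid weight for
  consistency; with consortium-scale ratio noise (se ≈ 0.4 per ratio) even
  the penalized median retains bias of order 0.02 under strong directional
  pleiotropy — the estimator bounds the damage, it does not eliminate it.
- Duplicate SNP ids keep the first occurrence with a warning; file
  round-trips are bit-exact on the canonical dialect (floats serialized via
  `repr`).
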