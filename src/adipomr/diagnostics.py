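"""Heterogeneity and pleiotropy diagnostics for summary-data MR.

If every instrument is valid, all per-SNP Wald ratios estimate the same
causal parameter; excess dispersion (Cochran's Q, I-squared) therefore
signals pleiotropic variants, and funnel-plot asymmetry (Egger's test)
signals *directional* pleiotropy that biases the IVW estimate.  This module
also implements the single-pass "remove heterogeneous variants and
re-estimate" sensitivity analysis: SNPs whose Q contribution exceeds the
chi-square(1) 95th percentile (3.84) are dropped and the IVW model re-run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .estimators import MREstimate, ivw, mr_egger
from .sumstats import HarmonizedSet

__all__ = [
    "HeterogeneityReport",
    "AsymmetryReport",
    "cochran_q",
    "i2_confidence_interval",
    "egger_asymmetry_test",
    "remove_heterogeneous_and_reestimate",
    "DEFAULT_FLAG_THRESHOLD",
]

# chi-square(1) upper 5% point; per-SNP Q contributions above this flag a
# variant as heterogeneous
DEFAULT_FLAG_THRESHOLD = float(stats.chi2.ppf(0.95, df=1))


@dataclass
class HeterogeneityReport:
    Q: float
    df: int
    p_het: float
    i2: float
    i2_ci_low: float
    i2_ci_high: float
    per_snp_q: dict[str, float] = field(default_factory=dict)
    flagged: list[str] = field(default_factory=list)


@dataclass
class AsymmetryReport:
    egger_intercept: float
    intercept_se: float
    p_asym: float
    funnel_points: list[tuple[float, float]] = field(default_factory=list)


def i2_confidence_interval(Q: float, df: int) -> tuple[float, float]:
    """Test-based 95% CI for I-squared via the log-H transformation.

    H = sqrt(Q/df); the standard error of ln H is taken from the Q-based
    formula when Q > df + 1 and from the null-side approximation otherwise,
    the interval back-transformed through I^2 = 100 * (H^2 - 1) / H^2 and
    truncated at 0.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    Q = float(Q)
    H = np.sqrt(max(Q, 1e-12) / df)
    lnH = max(0.0, np.log(H))
    if Q > df + 1:
        se_lnH = 0.5 * (np.log(Q) - np.log(df)) / (np.sqrt(2 * Q) - np.sqrt(2 * df - 1))
    elif df >= 2:
        se_lnH = np.sqrt(1.0 / (2 * (df - 1)) * (1.0 - 1.0 / (3 * (df - 1) ** 2)))
    else:
        # df = 1 with Q <= 2: the null-side formula is undefined; fall back
        # to the Q-branch formula evaluated just above the boundary
        Qb = df + 1e-6
        se_lnH = 0.5 * (np.log(Qb) - np.log(df)) / (np.sqrt(2 * Qb) - np.sqrt(2 * df - 1))
    z = stats.norm.ppf(0.975)

    def _to_i2(lnh):
        h2 = np.exp(2.0 * lnh)
        return float(max(0.0, (h2 - 1.0) / h2) * 100.0)

    return _to_i2(lnH - z * se_lnH), _to_i2(lnH + z * se_lnH)


def cochran_q(
    hset: HarmonizedSet,
    reference_beta: Optional[float] = None,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
) -> HeterogeneityReport:
    """Cochran's Q over per-SNP Wald ratios with I-squared and 95% CI.

    Each SNP contributes Q_j = w_j (beta_j - reference)^2 with
    w_j = gamma_j^2 / se_Gamma_j^2 and beta_j = Gamma_j / gamma_j.  The
    reference defaults to the full-set fixed-effect IVW estimate.  SNPs with
    Q_j above ``flag_threshold`` are flagged as heterogeneous.
    """
    if hset.k < 2:
        raise ValueError(f"Cochran's Q requires k >= 2, got {hset.k}")
    if reference_beta is None:
        reference_beta = ivw(hset, variance_model="fixed").beta
    ratios = hset.Gamma / hset.gamma
    w = hset.gamma**2 / hset.se_Gamma**2
    qj = w * (ratios - reference_beta) ** 2
    Q = float(np.sum(qj))
    df = hset.k - 1
    i2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    lo, hi = i2_confidence_interval(Q, df)
    return HeterogeneityReport(
        Q=Q,
        df=df,
        p_het=float(stats.chi2.sf(Q, df)),
        i2=float(i2),
        i2_ci_low=lo,
        i2_ci_high=hi,
        per_snp_q={s: float(q) for s, q in zip(hset.snp_ids, qj)},
        flagged=[s for s, q in zip(hset.snp_ids, qj) if q > flag_threshold],
    )


def egger_asymmetry_test(hset: HarmonizedSet) -> AsymmetryReport:
    """Funnel-plot asymmetry via the MR-Egger intercept test.

    Funnel coordinates are (precision 1/se(beta_j), beta_j) for the per-SNP
    Wald ratios; the asymmetry statistic is the analytic MR-Egger intercept
    (data oriented to positive gamma) with its two-sided normal p-value.
    """
    if hset.k < 3:
        raise ValueError(f"asymmetry test requires k >= 3, got {hset.k}")
    ratios = hset.Gamma / hset.gamma
    ratio_se = hset.se_Gamma / np.abs(hset.gamma)
    _, intercept = mr_egger(hset, boot=None)
    return AsymmetryReport(
        egger_intercept=intercept.beta,
        intercept_se=intercept.se,
        p_asym=intercept.pvalue,
        funnel_points=[(float(1.0 / s), float(r)) for s, r in zip(ratio_se, ratios)],
    )


def remove_heterogeneous_and_reestimate(
    hset: HarmonizedSet,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
    variance_model: str = "fixed",
) -> tuple[HarmonizedSet, MREstimate, HeterogeneityReport]:
    """Drop SNPs flagged by Cochran's Q and re-run IVW on the remainder.

    A single pass: Q contributions are computed against the full-set IVW
    estimate, flagged SNPs dropped, and IVW refit once.  Repeating the pass
    on the reduced set may flag further SNPs; that iteration is deliberately
    not applied.  Returns the reduced set, the new estimate, and the
    heterogeneity report used for removal.
    """
    if hset.k < 2:
        raise ValueError(f"removal requires k >= 2, got {hset.k}")
    report = cochran_q(hset, flag_threshold=flag_threshold)
    flagged = set(report.flagged)
    keep = [i for i, s in enumerate(hset.snp_ids) if s not in flagged]
    if not keep:
        raise ValueError("all SNPs flagged as heterogeneous; nothing to re-estimate")
    reduced = hset.subset(keep)
    reduced.dropped = list(hset.dropped) + [
        (s, f"Q contribution > {flag_threshold:.3g}") for s in report.flagged
    ]
    return reduced, ivw(reduced, variance_model=variance_model), report


def funnel_table(hset: HarmonizedSet, report: Optional[HeterogeneityReport] = None):
    """Per-SNP table (snp_id, ratio, se, precision, q_contribution, flagged)
    for funnel/forest exports."""
    import pandas as pd

    if report is None:
        report = cochran_q(hset)
    ratios = hset.Gamma / hset.gamma
    ses = hset.se_Gamma / np.abs(hset.gamma)
    return pd.DataFrame(
        {
            "snp_id": hset.snp_ids,
            "ratio": ratios,
            "se": ses,
            "precision": 1.0 / ses,
            "q_contribution": [report.per_snp_q[s] for s in hset.snp_ids],
            "flagged": [s in set(report.flagged) for s in hset.snp_ids],
        }
    )
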