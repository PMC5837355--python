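"""Causal-effect estimators for two-sample summary-data Mendelian randomization.

All estimators operate on a :class:`~adipomr.sumstats.HarmonizedSet` of
allele-aligned SNP-exposure (gamma_j, se_gamma_j) and SNP-outcome
(Gamma_j, se_Gamma_j) estimates and return :class:`MREstimate` records
in SD-of-outcome per SD-of-exposure units.

Methods
-------
wald_ratio
    Per-SNP ratio estimate Gamma_j / gamma_j with first-order delta SE.
ivw
    Inverse-variance weighted combination of the Wald ratios — identical to
    weighted least squares of Gamma on gamma through the origin with weights
    1/se_Gamma^2.  Fixed-effect by default; a multiplicative random-effects
    variant inflates the SE by max(1, sqrt(Q/(k-1))).
multivariable_ivw
    Origin-constrained weighted regression of Gamma on two exposures'
    gammas jointly, giving mutually adjusted causal effects.
mr_egger
    Weighted regression with an unconstrained intercept; the slope is the
    causal effect under the InSIDE assumption and the intercept estimates
    average directional pleiotropy.  SNPs are oriented to positive gamma
    first, since the regression is not orientation-invariant.
weighted_median
    The 50% point of the weight-ordered Wald ratios; with penalization,
    heterogeneous variants are down-weighted via their Cochran Q
    contribution.  Consistent while valid instruments carry >50% of weight.

Confidence intervals are normal-theory for wald/ivw/multivariable_ivw and
percentile-bootstrap (SNP resampling) for mr_egger and weighted_median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSet

__all__ = [
    "MREstimate",
    "BootstrapConfig",
    "wald_ratio",
    "ivw",
    "multivariable_ivw",
    "mr_egger",
    "weighted_median",
    "reverse_mr",
    "InsufficientInstrumentsError",
]

Z95 = stats.norm.ppf(0.975)


class InsufficientInstrumentsError(ValueError):
    pass


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its uncertainty.

    ``beta`` is in SD units of the outcome per SD of the exposure; ``k`` is
    the number of instruments used.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    exposure_name: str = "exposure"

    def __post_init__(self):
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValueError(
                f"{self.method}: CI [{self.ci_low}, {self.ci_high}] "
                f"does not bracket beta={self.beta}"
            )
        if not self.se > 0:
            raise ValueError(f"{self.method}: nonpositive SE {self.se}")


@dataclass(frozen=True)
class BootstrapConfig:
    """SNP-level resampling configuration for bootstrap CIs."""

    n_boot: int = 1000
    seed: int = 0
    ci_method: str = "percentile"

    def __post_init__(self):
        if self.n_boot < 100:
            raise ValueError(f"n_boot must be >= 100, got {self.n_boot}")
        if self.ci_method != "percentile":
            raise ValueError(f"unsupported ci_method {self.ci_method!r}")


def _normal_estimate(method, beta, se, k, exposure_name) -> MREstimate:
    z = beta / se
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        k=int(k),
        exposure_name=exposure_name,
    )


def wald_ratio(
    gamma: float, se_gamma: float, Gamma: float, se_Gamma: float,
    exposure_name: str = "exposure",
) -> MREstimate:
    """Single-SNP causal estimate Gamma/gamma with first-order delta SE.

    The first-order SE, se_Gamma/|gamma|, ignores uncertainty in gamma and
    understates the sampling SD of the ratio for weak instruments.
    """
    if gamma == 0:
        raise ZeroDivisionError("Wald ratio undefined: SNP-exposure beta is zero")
    return _normal_estimate(
        "wald", Gamma / gamma, se_Gamma / abs(gamma), 1, exposure_name
    )


def ivw(
    hset: HarmonizedSet, variance_model: str = "fixed"
) -> MREstimate:
    """Inverse-variance weighted estimate.

    beta = sum(gamma_j * Gamma_j / se_Gamma_j^2) / sum(gamma_j^2 / se_Gamma_j^2),
    the origin-constrained WLS slope of Gamma on gamma with weights
    1/se_Gamma^2.  ``variance_model`` is "fixed" (SE from the weighted
    normal equations) or "multiplicative_random" (SE inflated by
    max(1, sqrt(Q/(k-1))) to absorb between-instrument heterogeneity).
    """
    if hset.k == 0:
        raise InsufficientInstrumentsError("IVW requires at least one instrument")
    if variance_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown variance model {variance_model!r}")
    w = 1.0 / hset.se_Gamma**2
    denom = np.sum(hset.gamma**2 * w)
    beta = np.sum(hset.gamma * hset.Gamma * w) / denom
    se = denom**-0.5
    if variance_model == "multiplicative_random" and hset.k > 1:
        Q = np.sum(w * (hset.Gamma - beta * hset.gamma) ** 2)
        se *= max(1.0, np.sqrt(Q / (hset.k - 1)))
    return _normal_estimate("ivw", beta, se, hset.k, hset.exposure_name)


def multivariable_ivw(hset: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """Multivariable IVW: mutually adjusted effects of two exposures.

    Origin-constrained weighted least squares of Gamma on (gamma, gamma2)
    with weights 1/se_Gamma^2; per-coefficient SEs from the inverse weighted
    normal-equations matrix.
    """
    if hset.gamma2 is None:
        raise ValueError("multivariable IVW needs a second exposure (gamma2)")
    if hset.k < 3:
        raise InsufficientInstrumentsError(
            f"multivariable IVW requires k >= 3, got {hset.k}"
        )
    if np.all(hset.gamma2 == 0):
        # degenerate orthogonal case: a null second exposure carries no
        # information, and the exposure-1 coefficient reduces to the
        # univariable IVW estimate
        uni = ivw(hset, variance_model="fixed")
        est1 = _normal_estimate("mv_ivw", uni.beta, uni.se, hset.k, hset.exposure_name)
        est2 = MREstimate(
            method="mv_ivw", beta=0.0, se=np.inf, ci_low=-np.inf, ci_high=np.inf,
            pvalue=1.0, k=hset.k, exposure_name=hset.exposure2_name or "exposure2",
        )
        return est1, est2
    X = np.column_stack([hset.gamma, hset.gamma2])
    w = 1.0 / hset.se_Gamma**2
    XtWX = X.T @ (X * w[:, None])
    cond = np.linalg.cond(XtWX)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "exposure effect vectors are collinear; multivariable fit is rank-deficient"
        )
    coef = np.linalg.solve(XtWX, X.T @ (w * hset.Gamma))
    cov = np.linalg.inv(XtWX)
    ses = np.sqrt(np.diag(cov))
    est1 = _normal_estimate("mv_ivw", coef[0], ses[0], hset.k, hset.exposure_name)
    est2 = _normal_estimate(
        "mv_ivw", coef[1], ses[1], hset.k, hset.exposure2_name or "exposure2"
    )
    return est1, est2


def _orient_positive(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint sign-flip so every SNP-exposure beta is positive."""
    sign = np.where(hset.gamma < 0, -1.0, 1.0)
    return hset.gamma * sign, hset.Gamma * sign, hset.se_Gamma


def _egger_fit(g, G, sG, fit_intercept=True):
    """Weighted regression of G on g; returns (coefs, analytic SEs).

    SEs use a multiplicative overdispersion factor floored at 1 (residual
    variance estimated from the weighted fit, never deflated below the
    fixed-effect value).
    """
    w = 1.0 / sG**2
    X = np.column_stack([np.ones_like(g), g]) if fit_intercept else g[:, None]
    XtWX = X.T @ (X * w[:, None])
    coef = np.linalg.solve(XtWX, X.T @ (w * G))
    resid = G - X @ coef
    df = len(g) - X.shape[1]
    phi = max(1.0, float(np.sum(w * resid**2) / df)) if df > 0 else 1.0
    ses = np.sqrt(phi * np.diag(np.linalg.inv(XtWX)))
    return coef, ses


def _percentile_ci(draws: np.ndarray, point: float) -> tuple[float, float, float]:
    """(ci_low, ci_high, bootstrap SD), interval widened to bracket the point.

    The SD is floored at a tiny positive value so degenerate resamples
    (e.g. all Wald ratios identical) keep a valid estimate record.
    """
    lo, hi = np.percentile(draws, [2.5, 97.5])
    sd = max(float(np.std(draws, ddof=1)), 1e-12)
    return float(min(lo, point)), float(max(hi, point)), sd


def mr_egger(
    hset: HarmonizedSet,
    boot: Optional[BootstrapConfig] = None,
    fit_intercept: bool = True,
) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    The slope estimates the causal effect even when all instruments are
    invalid, provided instrument strength is independent of the direct
    (pleiotropic) effects (InSIDE); the intercept estimates the average
    directional pleiotropy.  SNPs are first oriented so every gamma_j > 0.
    With ``boot`` given, 95% CIs come from percentile bootstrap over SNPs
    and p-values from the bootstrap-SD normal approximation; otherwise both
    are analytic.  ``fit_intercept=False`` constrains the intercept to zero,
    collapsing to the fixed-effect IVW slope (internal check mode).
    """
    if hset.k < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires k >= 3, got {hset.k}")
    g, G, sG = _orient_positive(hset)
    coef, ses = _egger_fit(g, G, sG, fit_intercept)
    if not fit_intercept:
        slope = _normal_estimate("egger_slope", coef[0], ses[0], hset.k, hset.exposure_name)
        return slope, None

    if boot is None:
        # analytic p-values use t with k-2 df, the usual small-sample
        # reference for the Egger regression
        def _t_estimate(name, b, s):
            tval = b / s
            return MREstimate(
                method=name, beta=float(b), se=float(s),
                ci_low=float(b - Z95 * s), ci_high=float(b + Z95 * s),
                pvalue=float(2.0 * stats.t.sf(abs(tval), df=hset.k - 2)),
                k=hset.k, exposure_name=hset.exposure_name,
            )

        return (
            _t_estimate("egger_slope", coef[1], ses[1]),
            _t_estimate("egger_intercept", coef[0], ses[0]),
        )

    rng = np.random.default_rng(boot.seed)
    k = hset.k
    draws = np.empty((boot.n_boot, 2))
    for b in range(boot.n_boot):
        idx = rng.integers(0, k, size=k)
        draws[b], _ = _egger_fit(g[idx], G[idx], sG[idx], True)
    out = []
    for j, (name, analytic_se) in enumerate(
        [("egger_intercept", ses[0]), ("egger_slope", ses[1])]
    ):
        lo, hi, bsd = _percentile_ci(draws[:, j], coef[j])
        out.append(
            MREstimate(
                method=name,
                beta=float(coef[j]),
                se=float(analytic_se),
                ci_low=lo,
                ci_high=hi,
                pvalue=float(2.0 * stats.norm.sf(abs(coef[j]) / bsd)),
                k=k,
                exposure_name=hset.exposure_name,
            )
        )
    return out[1], out[0]


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: sort ratios, form normalized cumulative
    weights at midpoints s_j = (cumsum(w)_j - w_j/2) / sum(w), and linearly
    interpolate the ratio at s = 0.5."""
    order = np.argsort(ratios)
    b = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if 0.5 <= s[0]:
        return float(b[0])
    if 0.5 >= s[-1]:
        return float(b[-1])
    return float(np.interp(0.5, s, b))


def weighted_median(
    hset: HarmonizedSet,
    penalized: bool = False,
    penalty_scale: float = 20.0,
    boot: Optional[BootstrapConfig] = None,
) -> MREstimate:
    """(Penalized) weighted median of the per-SNP Wald ratios.

    Weights are the inverse first-order ratio variances,
    w_j = gamma_j^2 / se_Gamma_j^2.  With ``penalized``, each SNP's Cochran
    Q contribution against the unpenalized weighted-median estimate is
    converted to an upper-tail chi-square(1) probability q_j and the weight
    multiplied by min(1, penalty_scale * q_j), down-weighting heterogeneous
    (likely pleiotropic) variants.  CI by percentile bootstrap over SNPs.
    """
    if hset.k < 3:
        raise InsufficientInstrumentsError(
            f"weighted median requires k >= 3, got {hset.k}"
        )
    ratios = hset.Gamma / hset.gamma
    weights = hset.gamma**2 / hset.se_Gamma**2

    def _estimate(b, w):
        if penalized:
            est0 = _weighted_median_point(b, w)
            Qj = w * (b - est0) ** 2
            qj = stats.chi2.sf(Qj, df=1)
            w = w * np.minimum(1.0, penalty_scale * qj)
            if np.all(w == 0):
                raise ValueError("all weights zero after penalization")
        return _weighted_median_point(b, w)

    point = _estimate(ratios, weights)
    cfg = boot or BootstrapConfig()
    rng = np.random.default_rng(cfg.seed)
    k = hset.k
    draws = np.empty(cfg.n_boot)
    for bi in range(cfg.n_boot):
        idx = rng.integers(0, k, size=k)
        try:
            draws[bi] = _estimate(ratios[idx], weights[idx])
        except ValueError:
            draws[bi] = point
    lo, hi, bsd = _percentile_ci(draws, point)
    return MREstimate(
        method="penalized_weighted_median" if penalized else "weighted_median",
        beta=point,
        se=bsd,
        ci_low=lo,
        ci_high=hi,
        pvalue=float(2.0 * stats.norm.sf(abs(point) / bsd)),
        k=k,
        exposure_name=hset.exposure_name,
    )


def reverse_mr(hset: HarmonizedSet, variance_model: str = "fixed") -> MREstimate:
    """IVW with the exposure/outcome roles as given in a reverse-direction
    harmonized set (e.g. adiponectin instruments against girth outcomes).

    The computation is identical to :func:`ivw`; only the method label
    distinguishes the reversed causal direction.
    """
    est = ivw(hset, variance_model=variance_model)
    return MREstimate(
        method="reverse_ivw",
        beta=est.beta,
        se=est.se,
        ci_low=est.ci_low,
        ci_high=est.ci_high,
        pvalue=est.pvalue,
        k=est.k,
        exposure_name=hset.exposure_name,
    )
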