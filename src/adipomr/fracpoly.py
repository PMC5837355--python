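"""Fractional-polynomial dose-response models for the cohort arm.

Complements the genetic analysis with individual-level modelling: linear
regressions of standardized log adiponectin on standardized fat-depot
measures, and two-degree fractional-polynomial (FP2) fits over the
conventional power set S = {-2, -1, -0.5, 0, 0.5, 1, 2, 3} to detect
nonlinear depot-adiponectin relations (power 0 denotes ln x; a repeated
power (p, p) contributes x^p and x^p ln x).  The best FP2 model is compared
with the linear model by a likelihood-ratio test on 3 df (two power choices
plus one coefficient), with Bonferroni correction across depot-by-sex
models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FP_POWERS",
    "FPFit",
    "fp_basis",
    "fp2_fit",
    "bonferroni_threshold",
    "standardized_regression",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)
LR_DF = 3  # FP2 adds two power choices and one coefficient vs linear


@dataclass
class FPFit:
    """Best two-degree fractional-polynomial fit for one depot."""

    powers: tuple[float, float]
    deviance: float
    coefficients: np.ndarray
    lr_p_vs_linear: float
    linear_deviance: float
    lr_stat: float
    n: int
    all_deviances: dict[tuple[float, float], float] = field(default_factory=dict)


def _power_term(x: np.ndarray, p: float) -> np.ndarray:
    return np.log(x) if p == 0 else x**p


def fp_basis(x: np.ndarray, p1: float, p2: float) -> np.ndarray:
    """Two-column FP2 basis for strictly positive x.

    x^0 means ln x; a repeated power (p, p) maps to (x^p, x^p ln x).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fractional polynomial basis requires strictly positive x")
    t1 = _power_term(x, p1)
    t2 = t1 * np.log(x) if p1 == p2 else _power_term(x, p2)
    return np.column_stack([t1, t2])


def _shift_positive(x: np.ndarray) -> np.ndarray:
    """Shift rule for nonpositive depot values: add half the smallest
    positive value; error if any value remains nonpositive."""
    if np.all(x > 0):
        return x
    positive = x[x > 0]
    if positive.size == 0:
        raise ValueError("all depot values nonpositive; cannot shift")
    shifted = x + positive.min() / 2.0
    if np.any(shifted <= 0):
        raise ValueError("depot values nonpositive after shift")
    return shifted


def _ols_deviance(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    model = sm.OLS(y, X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    res = model.fit()
    return float(-2.0 * res.llf), np.asarray(res.params)


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def fp2_fit(
    records: pd.DataFrame,
    depot_name: str,
    outcome: str = "log_adiponectin",
    covariates: Sequence[str] = (),
) -> FPFit:
    """Fit all 36 FP2 power pairs for one depot and test against linearity.

    ``records`` is a complete-case table (typically already restricted to
    one sex).  Every FP2 model regresses the outcome on the two transformed
    depot columns plus an intercept and any covariates, by Gaussian OLS; the
    minimum-deviance pair wins.  The likelihood-ratio statistic against the
    corresponding linear model is referred to chi-square(3).
    """
    y = records[outcome].to_numpy(dtype=float)
    x = _shift_positive(records[depot_name].to_numpy(dtype=float))
    n = len(y)
    cov = (
        records[list(covariates)].to_numpy(dtype=float)
        if covariates
        else np.empty((n, 0))
    )
    base = np.column_stack([np.ones(n), cov])
    if n <= base.shape[1] + 2:
        raise ValueError(f"n={n} too small for FP2 with {base.shape[1]} base columns")

    lin_dev, _ = _ols_deviance(y, np.column_stack([base, _zscore(x)]))

    best: Optional[tuple[float, tuple[float, float], np.ndarray]] = None
    devs: dict[tuple[float, float], float] = {}
    for p1, p2 in itertools.combinations_with_replacement(FP_POWERS, 2):
        B = fp_basis(x, p1, p2)
        # standardize transformed columns for numerical balance (does not
        # change the Gaussian log-likelihood)
        B = (B - B.mean(axis=0)) / B.std(axis=0, ddof=1)
        dev, coefs = _ols_deviance(y, np.column_stack([base, B]))
        devs[(p1, p2)] = dev
        if best is None or dev < best[0]:
            best = (dev, (p1, p2), coefs)

    dev, powers, coefs = best
    lr = max(0.0, lin_dev - dev)
    return FPFit(
        powers=powers,
        deviance=dev,
        coefficients=coefs,
        lr_p_vs_linear=float(stats.chi2.sf(lr, LR_DF)),
        linear_deviance=lin_dev,
        lr_stat=lr,
        n=n,
        all_deviances=devs,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance threshold alpha/m for m comparisons."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return alpha / m


def standardized_regression(
    records: pd.DataFrame,
    depot_name: str,
    adjusted: bool = False,
    outcome: str = "log_adiponectin",
    covariates: Sequence[str] = (),
    other_depots: Sequence[str] = (),
) -> pd.DataFrame:
    """OLS of standardized outcome on standardized depot, optionally adjusted.

    Outcome and all depot columns are z-scored within the supplied table
    (callers stratify by sex first, mirroring within-sex standardization),
    so coefficients are in SD-per-SD units.  Adjusted models add the listed
    covariates and the other depots.  Returns a tidy coefficient table with
    SEs, normal-theory 95% CIs and p-values.
    """
    y = _zscore(records[outcome].to_numpy(dtype=float))
    cols = [depot_name] + (list(other_depots) if adjusted else [])
    X_parts = [_zscore(records[c].to_numpy(dtype=float)) for c in cols]
    names = ["intercept"] + cols
    if adjusted and covariates:
        for c in covariates:
            X_parts.append(records[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack([np.ones(len(y))] + X_parts)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    res = sm.OLS(y, X).fit()
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "term": names,
            "beta": res.params,
            "se": res.bse,
            "ci_low": res.params - z * res.bse,
            "ci_high": res.params + z * res.bse,
            "pvalue": 2.0 * stats.norm.sf(np.abs(res.params / res.bse)),
        }
    )
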