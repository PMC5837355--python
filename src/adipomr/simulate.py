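"""Synthetic data with the statistical structure the MR analysis assumes.

Two generators:

``simulate_two_sample``
    Consortium-style GWAS summary statistics for one or two correlated
    exposures (waist-like and hip-like girth traits) and an outcome
    (log adiponectin), with non-overlapping exposure and outcome samples,
    configurable horizontal pleiotropy (balanced or directional, with an
    optional InSIDE violation), and standard errors at consortium scale,
    se = 1/sqrt(2 * MAF * (1 - MAF) * n) on the standardized-trait scale.

``simulate_cohort``
    An individual-level cohort table of correlated fat-depot measures
    (raw scales matched to published adult-cohort means/SDs), lifestyle and
    ancestry covariates, and log adiponectin generated from a linear or
    deliberately nonlinear (U-shaped) depot dose-response.

Everything is driven by a single integer seed and is reproducible draw for
draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .sumstats import COMPLEMENT, HarmonizedSet, SNPAssociation, SummaryDataset

__all__ = [
    "PleiotropyConfig",
    "SimulationConfig",
    "TwoSampleSimulation",
    "simulate_two_sample",
    "simulate_harmonized",
    "simulate_cohort",
    "PAPER_WAIST_SCENARIO",
    "PAPER_HIP_SCENARIO",
]

_ALLELE_PAIRS = [
    (a, b) for a in "ACGT" for b in "ACGT" if a != b
]  # includes palindromic A/T and C/G pairs


@dataclass(frozen=True)
class PleiotropyConfig:
    """Horizontal-pleiotropy regime for invalid instruments.

    ``fraction_invalid`` of SNPs receive a direct effect on the outcome,
    drawn Normal(mean, sd^2); ``directional=False`` forces mean 0 (balanced
    pleiotropy).  ``inside_violation`` correlates the direct effects with
    instrument strength, breaking the InSIDE assumption MR-Egger relies on.
    """

    fraction_invalid: float = 0.0
    mean: float = 0.0
    sd: float = 0.0
    directional: bool = False
    inside_violation: bool = False

    def __post_init__(self):
        if not 0.0 <= self.fraction_invalid <= 1.0:
            raise ValueError(f"fraction_invalid outside [0,1]: {self.fraction_invalid}")
        if self.sd < 0:
            raise ValueError(f"negative pleiotropy sd: {self.sd}")


@dataclass(frozen=True)
class SimulationConfig:
    """True parameters for a two-sample summary-statistic simulation.

    Defaults mirror the abdominal-fat scenario: 56 instruments, causal
    effect -0.27 SD log adiponectin per SD waist circumference, exposure
    GWAS n = 210 088, outcome GWAS n = 29 347, and per-SNP effect spread
    (``gamma_sd`` = 0.024) sized so the instruments explain about 1.2% of
    exposure variance.
    """

    k_snps: int = 56
    beta_true: float = -0.27
    beta2_true: Optional[float] = None
    n_exposure: int = 210_088
    n_outcome: int = 29_347
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_sd: float = 0.024
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    exposure_correlation: float = 0.5
    seed: int = 0
    noise_free: bool = False

    def __post_init__(self):
        if self.k_snps < 1:
            raise ValueError("k_snps must be >= 1")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5: {self.maf_range}")
        if not -1 < self.exposure_correlation < 1:
            raise ValueError("exposure_correlation must be in (-1, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "rt") as fh:
            raw = yaml.safe_load(fh)
        if "pleiotropy" in raw and isinstance(raw["pleiotropy"], dict):
            raw["pleiotropy"] = PleiotropyConfig(**raw["pleiotropy"])
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["maf_range"] = list(self.maf_range)
        with open(path, "wt") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# the study-scale scenarios: instrument counts, sample sizes and causal
# effects at which the published analysis operated
PAPER_WAIST_SCENARIO = SimulationConfig(k_snps=56, beta_true=-0.27, gamma_sd=0.024)
# hip instruments explain ~2.0% of variance across 75 SNPs -> gamma_sd 0.027
PAPER_HIP_SCENARIO = SimulationConfig(k_snps=75, beta_true=0.17, gamma_sd=0.027)


@dataclass
class TwoSampleSimulation:
    exposure: SummaryDataset
    outcome: SummaryDataset
    exposure2: Optional[SummaryDataset]
    truth: dict


def _draw_latents(config: SimulationConfig, rng: np.random.Generator) -> dict:
    k = config.k_snps
    maf = rng.uniform(*config.maf_range, size=k)
    if config.beta2_true is not None:
        rho = config.exposure_correlation
        cov = config.gamma_sd**2 * np.array([[1.0, rho], [rho, 1.0]])
        gammas = rng.multivariate_normal([0.0, 0.0], cov, size=k)
        gamma, gamma2 = gammas[:, 0], gammas[:, 1]
    else:
        gamma = rng.normal(0.0, config.gamma_sd, size=k)
        gamma2 = None
    ple = config.pleiotropy
    alpha = np.zeros(k)
    n_invalid = int(round(ple.fraction_invalid * k))
    if n_invalid > 0:
        invalid = rng.choice(k, size=n_invalid, replace=False)
        mean = ple.mean if ple.directional else 0.0
        direct = rng.normal(mean, ple.sd, size=n_invalid)
        if ple.inside_violation:
            # couple direct effects to instrument strength (breaks InSIDE)
            direct = direct + 0.5 * np.abs(gamma[invalid]) / config.gamma_sd * ple.sd
        if ple.directional:
            # directional pleiotropy is defined relative to the
            # exposure-raising allele: couple the sign to gamma so the mean
            # direct effect after orientation equals ``mean``
            direct = direct * np.sign(gamma[invalid])
        alpha[invalid] = direct
    Gamma = config.beta_true * gamma + alpha
    if gamma2 is not None:
        Gamma = Gamma + config.beta2_true * gamma2
    se_g = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_G = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)
    return dict(
        maf=maf, gamma_true=gamma, gamma2_true=gamma2, alpha=alpha,
        Gamma_true=Gamma, se_gamma=se_g, se_Gamma=se_G,
        beta_true=config.beta_true, beta2_true=config.beta2_true,
    )


def _observe(true: np.ndarray, se: np.ndarray, rng, noise_free: bool) -> np.ndarray:
    return true.copy() if noise_free else rng.normal(true, se)


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    return np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), 1e-300, 1.0)


def simulate_harmonized(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[HarmonizedSet, dict]:
    """Fast path: draw a two-sample dataset directly on the harmonized scale.

    Skips allele bookkeeping (every SNP already expressed per effect-allele
    copy) — the workhorse for Monte-Carlo studies.  Returns (HarmonizedSet,
    truth record).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lat = _draw_latents(config, rng)
    g = _observe(lat["gamma_true"], lat["se_gamma"], rng, config.noise_free)
    G = _observe(lat["Gamma_true"], lat["se_Gamma"], rng, config.noise_free)
    g2 = None
    if lat["gamma2_true"] is not None:
        g2 = _observe(lat["gamma2_true"], lat["se_gamma"], rng, config.noise_free)
    ids = [f"rs{i + 1}" for i in range(config.k_snps)]
    hset = HarmonizedSet(
        snp_ids=ids,
        gamma=g,
        se_gamma=lat["se_gamma"],
        Gamma=G,
        se_Gamma=lat["se_Gamma"],
        gamma2=g2,
        se_gamma2=None if g2 is None else lat["se_gamma"].copy(),
        exposure_name="exposure1",
        exposure2_name="exposure2" if g2 is not None else None,
        outcome_name="outcome",
        eaf=lat["maf"].copy(),
    )
    return hset, lat


def simulate_two_sample(config: SimulationConfig) -> TwoSampleSimulation:
    """Generate exposure/outcome SummaryDatasets with full allele bookkeeping.

    The exposure and outcome association estimates are drawn independently
    (two non-overlapping samples).  Alleles are assigned at random,
    including palindromic A/T and C/G pairs, and the outcome (and second
    exposure) records are independently re-expressed on the opposite allele
    or strand at random, so harmonization is genuinely exercised.  The truth
    record carries every latent value.
    """
    rng = np.random.default_rng(config.seed)
    lat = _draw_latents(config, rng)
    k = config.k_snps
    ids = [f"rs{i + 1}" for i in range(k)]
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), size=k)]
    eaf = np.where(rng.random(k) < 0.5, lat["maf"], 1.0 - lat["maf"])

    g_obs = _observe(lat["gamma_true"], lat["se_gamma"], rng, config.noise_free)
    G_obs = _observe(lat["Gamma_true"], lat["se_Gamma"], rng, config.noise_free)
    g2_obs = (
        _observe(lat["gamma2_true"], lat["se_gamma"], rng, config.noise_free)
        if lat["gamma2_true"] is not None
        else None
    )

    def _records(betas, ses, n, scramble):
        p = _pvalues(betas, ses)
        recs = []
        for j in range(k):
            ea, oa = pairs[j]
            beta, f = float(betas[j]), float(eaf[j])
            if scramble and rng.random() < 0.5:  # report on the other allele
                ea, oa, beta, f = oa, ea, -beta, 1.0 - f
            if scramble and rng.random() < 0.5:  # report on the other strand
                ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
            recs.append(
                SNPAssociation(
                    snp_id=ids[j], effect_allele=ea, other_allele=oa,
                    eaf=f, beta=beta, se=float(ses[j]), pvalue=float(p[j]), n=n,
                )
            )
        return recs

    exposure = SummaryDataset(
        "exposure1", _records(g_obs, lat["se_gamma"], config.n_exposure, False),
        covariate_adjustments=["BMI"],
    )
    outcome = SummaryDataset(
        "outcome", _records(G_obs, lat["se_Gamma"], config.n_outcome, True)
    )
    exposure2 = None
    if g2_obs is not None:
        exposure2 = SummaryDataset(
            "exposure2", _records(g2_obs, lat["se_gamma"], config.n_exposure, True),
            covariate_adjustments=["BMI"],
        )
    truth = dict(lat, snp_ids=ids, eaf=eaf, config=config)
    return TwoSampleSimulation(exposure, outcome, exposure2, truth)


# ---------------------------------------------------------------------------
# individual-level cohort generator

# raw-scale depot means/SDs per sex: visceral and subcutaneous abdominal fat
# thickness in cm, gluteofemoral fat mass in kg (adult birth-cohort values)
DEPOT_SCALES = {
    "male": {
        "visceral_cm": (6.8, 1.9),
        "deep_sc_cm": (1.2, 0.7),
        "superficial_sc_cm": (0.7, 0.3),
        "gluteofemoral_kg": (3.7, 1.6),
    },
    "female": {
        "visceral_cm": (4.9, 1.6),
        "deep_sc_cm": (1.5, 0.8),
        "superficial_sc_cm": (1.0, 0.5),
        "gluteofemoral_kg": (5.4, 1.9),
    },
}

DEPOTS = list(DEPOT_SCALES["male"])

# adjusted depot -> standardized log-adiponectin effects (SD per SD); the
# mutual depot correlations make the unadjusted gluteofemoral association
# negative even though its adjusted effect is positive
DEFAULT_DEPOT_EFFECTS = {
    "visceral_cm": -0.24,
    "deep_sc_cm": -0.07,
    "superficial_sc_cm": -0.20,
    "gluteofemoral_kg": 0.13,
}

# visceral vs subcutaneous ~0.4; among subcutaneous depots ~0.6
DEFAULT_DEPOT_CORRELATIONS = np.array(
    [
        [1.0, 0.4, 0.4, 0.4],
        [0.4, 1.0, 0.6, 0.6],
        [0.4, 0.6, 1.0, 0.6],
        [0.4, 0.6, 0.6, 1.0],
    ]
)

_COVARIATE_EFFECTS = {"ancestry": -0.10, "activity": 0.05, "smoking": -0.05, "alcohol": -0.05}


def simulate_cohort(
    n: int,
    effects: Optional[dict[str, float]] = None,
    depot_correlations: Optional[np.ndarray] = None,
    nonlinearity: Optional[dict[str, dict]] = None,
    noise_sd: Optional[float] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Individual-level cohort table with correlated fat depots.

    ``effects`` are adjusted per-depot effects on standardized
    log adiponectin (SD per SD); ``nonlinearity`` maps a depot name to
    ``{"shape": "ushape", "strength": s}``, adding s * (z^2 - 1) to the
    linear predictor so the depot's dose-response is U-shaped.
    ``noise_sd=None`` sizes the residual so the outcome has roughly unit
    variance.  Participants split evenly between sexes; complete cases only.
    """
    effects = dict(DEFAULT_DEPOT_EFFECTS if effects is None else effects)
    R = DEFAULT_DEPOT_CORRELATIONS if depot_correlations is None else np.asarray(depot_correlations)
    eigvals = np.linalg.eigvalsh(R)
    if np.any(eigvals <= 0):
        raise ValueError("depot correlation matrix is not positive definite")
    rng = np.random.default_rng(seed)
    frames = []
    for sex in ("male", "female"):
        m = n // 2 if sex == "male" else n - n // 2
        z = rng.multivariate_normal(np.zeros(len(DEPOTS)), R, size=m)
        data = {"sex": np.repeat(sex, m)}
        for j, depot in enumerate(DEPOTS):
            mu, sd = DEPOT_SCALES[sex][depot]
            data[depot] = np.maximum(mu + sd * z[:, j], 0.05)
        data["ancestry"] = rng.beta(2.0, 8.0, size=m)
        data["activity"] = rng.integers(0, 3, size=m).astype(float)
        data["smoking"] = rng.integers(0, 4, size=m).astype(float)
        data["alcohol"] = rng.integers(0, 2, size=m).astype(float)

        pred = np.zeros(m)
        for j, depot in enumerate(DEPOTS):
            pred += effects.get(depot, 0.0) * z[:, j]
            nl = (nonlinearity or {}).get(depot)
            if nl:
                if nl.get("shape", "ushape") != "ushape":
                    raise ValueError(f"unknown nonlinearity shape {nl!r}")
                pred += nl["strength"] * (z[:, j] ** 2 - 1.0)
        for cov, eff in _COVARIATE_EFFECTS.items():
            pred += eff * (data[cov] - np.mean(data[cov]))
        if noise_sd is None:
            sd_resid = float(np.sqrt(max(1.0 - np.var(pred), 0.05)))
        else:
            sd_resid = noise_sd
        data["log_adiponectin"] = pred + rng.normal(0.0, sd_resid, size=m) \
            if sd_resid > 0 else pred
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
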