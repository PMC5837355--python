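"""End-to-end orchestration: selection -> harmonization -> estimation ->
diagnostics, plus repeated-simulation studies.

``run_full_analysis`` executes the complete two-sample MR workflow from
summary-statistic files: genome-wide filtering, LD pruning, cross-exposure
overlap exclusion, harmonization, the four estimators, stage-one
(heterogeneity/asymmetry) and stage-two (robust estimators, heterogeneous-
variant removal) sensitivity analyses, and an optional reverse-direction
analysis.  Every threshold, seed, count and drop reason lands in a
structured run log, and all tables are written as plain delimited text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from . import estimators as est
from . import instruments as instr
from . import sumstats as ss
from .simulate import SimulationConfig, simulate_harmonized

__all__ = [
    "AnalysisConfig",
    "run_full_analysis",
    "run_simulation_study",
    "write_harmonized",
    "read_harmonized",
]


@dataclass
class AnalysisConfig:
    """File paths, thresholds and method switches for a full analysis run."""

    exposure_path: str
    outcome_path: str
    second_exposure_path: Optional[str] = None
    ld_path: Optional[str] = None
    reverse_exposure_path: Optional[str] = None
    reverse_outcome_path: Optional[str] = None
    output_dir: str = "adipomr_output"
    gwas_p: float = 5e-8
    ld_r2: float = 0.05
    palindrome_window: float = 0.08
    flag_threshold: float = diag.DEFAULT_FLAG_THRESHOLD
    variance_model: str = "fixed"
    penalty_scale: float = 20.0
    n_boot: int = 1000
    seed: int = 0
    column_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.gwas_p <= 1):
            raise ValueError(f"gwas_p outside (0, 1]: {self.gwas_p}")
        if not (0 <= self.ld_r2 <= 1):
            raise ValueError(f"ld_r2 outside [0, 1]: {self.ld_r2}")
        if not (0 <= self.palindrome_window < 0.5):
            raise ValueError(f"palindrome_window outside [0, 0.5): {self.palindrome_window}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "rt") as fh:
            return cls(**yaml.safe_load(fh))


def _restrict(dataset: ss.SummaryDataset, ids) -> ss.SummaryDataset:
    idset = set(ids)
    return ss.SummaryDataset(
        trait_name=dataset.trait_name,
        records=[r for r in dataset.records if r.snp_id in idset],
        ancestry_label=dataset.ancestry_label,
        covariate_adjustments=list(dataset.covariate_adjustments),
    )


def _estimate_row(e: est.MREstimate) -> dict:
    return {
        "method": e.method, "exposure": e.exposure_name, "k": e.k,
        "beta": e.beta, "se": e.se, "ci_low": e.ci_low, "ci_high": e.ci_high,
        "pvalue": e.pvalue,
    }


def write_harmonized(hset: ss.HarmonizedSet, path) -> None:
    """Write a HarmonizedSet as a tab-delimited table (exposure-aligned betas)."""
    cols = {
        "snp_id": hset.snp_ids,
        "gamma": hset.gamma,
        "se_gamma": hset.se_gamma,
        "Gamma": hset.Gamma,
        "se_Gamma": hset.se_Gamma,
    }
    if hset.gamma2 is not None:
        cols["gamma2"] = hset.gamma2
        cols["se_gamma2"] = hset.se_gamma2
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_harmonized(path, exposure_name="exposure", outcome_name="outcome") -> ss.HarmonizedSet:
    df = pd.read_csv(path, sep="\t")
    return ss.HarmonizedSet(
        snp_ids=df["snp_id"].astype(str).tolist(),
        gamma=df["gamma"].to_numpy(float),
        se_gamma=df["se_gamma"].to_numpy(float),
        Gamma=df["Gamma"].to_numpy(float),
        se_Gamma=df["se_Gamma"].to_numpy(float),
        gamma2=df["gamma2"].to_numpy(float) if "gamma2" in df else None,
        se_gamma2=df["se_gamma2"].to_numpy(float) if "se_gamma2" in df else None,
        exposure_name=exposure_name,
        outcome_name=outcome_name,
    )


def _analyse_one_exposure(
    hset: ss.HarmonizedSet, config: AnalysisConfig, log: dict
) -> tuple[list[dict], dict]:
    """All univariable estimators plus both sensitivity stages for one exposure."""
    rows = []
    boot = est.BootstrapConfig(n_boot=config.n_boot, seed=config.seed)
    rows.append(_estimate_row(est.ivw(hset, variance_model=config.variance_model)))
    slope, intercept = est.mr_egger(hset, boot=boot)
    rows.append(_estimate_row(slope))
    rows.append(_estimate_row(intercept))
    rows.append(_estimate_row(est.weighted_median(hset, penalized=False, boot=boot)))
    rows.append(
        _estimate_row(
            est.weighted_median(
                hset, penalized=True, penalty_scale=config.penalty_scale, boot=boot
            )
        )
    )
    het = diag.cochran_q(hset, flag_threshold=config.flag_threshold)
    asym = diag.egger_asymmetry_test(hset)
    reduced, post, _ = diag.remove_heterogeneous_and_reestimate(
        hset, flag_threshold=config.flag_threshold, variance_model=config.variance_model
    )
    post_row = _estimate_row(post)
    post_row["method"] = "ivw_post_removal"
    rows.append(post_row)
    diagnostics = {
        "heterogeneity": {
            "Q": het.Q, "df": het.df, "p_het": het.p_het, "i2": het.i2,
            "i2_ci_low": het.i2_ci_low, "i2_ci_high": het.i2_ci_high,
            "n_flagged": len(het.flagged), "flagged": het.flagged,
        },
        "asymmetry": {
            "egger_intercept": asym.egger_intercept,
            "intercept_se": asym.intercept_se,
            "p_asym": asym.p_asym,
        },
        "funnel": diag.funnel_table(hset, het),
        "post_removal_k": post.k,
    }
    log[f"{hset.exposure_name}:removed_heterogeneous"] = het.flagged
    return rows, diagnostics


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Execute the full pipeline and write the report bundle to
    ``config.output_dir``.  Returns the bundle as a dict of DataFrames and
    dicts; partial outputs are written before any stage error propagates.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {k: v for k, v in asdict(config).items()}}
    bundle: dict = {"log": log}

    def _checkpoint():
        with open(out / "run_log.json", "wt") as fh:
            json.dump(log, fh, indent=2, default=str)

    try:
        exposure = ss.read_summary_table(
            config.exposure_path, config.column_map, trait_name="exposure1"
        )
        outcome = ss.read_summary_table(
            config.outcome_path, config.column_map, trait_name="outcome"
        )
        exposure2 = None
        if config.second_exposure_path:
            exposure2 = ss.read_summary_table(
                config.second_exposure_path, config.column_map, trait_name="exposure2"
            )
        log["stage:read"] = {
            "exposure_snps": len(exposure),
            "outcome_snps": len(outcome),
            "second_exposure_snps": None if exposure2 is None else len(exposure2),
        }

        ld = instr.read_ld_pairs(config.ld_path) if config.ld_path else instr.LDInfo()

        def _select(ds):
            cands = instr.filter_genomewide(ds, threshold=config.gwas_p)
            return instr.ld_prune(cands, ds, ld, r2_threshold=config.ld_r2)

        set1 = _select(exposure)
        sets = {"exposure1": set1}
        if exposure2 is not None:
            set2 = _select(exposure2)
            set1, set2, shared = instr.exclude_overlap(set1, set2)
            sets = {"exposure1": set1, "exposure2": set2}
            log["stage:overlap"] = {"n_shared_excluded": len(shared), "shared": shared}
        log["stage:selection"] = {name: len(s) for name, s in sets.items()}
        for name, s in sets.items():
            s.write(out / f"instruments_{name}.txt", out / f"instruments_{name}_log.tsv")
    except Exception:
        _checkpoint()
        raise

    rows: list[dict] = []
    diagnostics: dict = {}
    hsets: dict = {}
    try:
        datasets = {"exposure1": exposure}
        if exposure2 is not None:
            datasets["exposure2"] = exposure2
        for name, iset in sets.items():
            hset = ss.harmonize(
                _restrict(datasets[name], iset.snp_ids), outcome,
                palindromic_eaf_window=config.palindrome_window,
            )
            hsets[name] = hset
            log[f"stage:harmonize:{name}"] = {
                "retained": hset.k, "dropped": hset.dropped,
            }
            write_harmonized(hset, out / f"harmonized_{name}.tsv")
            ss.export_drop_audit(hset, out / f"drop_audit_{name}.tsv")
            erows, ediag = _analyse_one_exposure(hset, config, log)
            rows.extend(erows)
            diagnostics[name] = ediag
            ediag["funnel"].to_csv(out / f"funnel_{name}.tsv", sep="\t", index=False)

        if exposure2 is not None:
            union_ids = sets["exposure1"].snp_ids + sets["exposure2"].snp_ids
            mv_hset = ss.harmonize(
                _restrict(exposure, union_ids), outcome,
                second_exposure=_restrict(exposure2, union_ids),
                palindromic_eaf_window=config.palindrome_window,
            )
            hsets["multivariable"] = mv_hset
            e1, e2 = est.multivariable_ivw(mv_hset)
            rows.extend([_estimate_row(e1), _estimate_row(e2)])
            log["stage:multivariable"] = {"k": mv_hset.k}
        else:
            log["stage:multivariable"] = "skipped: no second exposure supplied"

        if config.reverse_exposure_path and config.reverse_outcome_path:
            rev = ss.harmonize(
                ss.read_summary_table(
                    config.reverse_exposure_path, config.column_map,
                    trait_name="outcome_as_exposure",
                ),
                ss.read_summary_table(
                    config.reverse_outcome_path, config.column_map,
                    trait_name="exposure_as_outcome",
                ),
                palindromic_eaf_window=config.palindrome_window,
            )
            rows.append(_estimate_row(est.reverse_mr(rev, config.variance_model)))
            log["stage:reverse"] = {"k": rev.k}
    finally:
        estimates = pd.DataFrame(rows)
        if len(estimates):
            estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
        _checkpoint()

    bundle.update(estimates=estimates, diagnostics=diagnostics, hsets=hsets)
    return bundle


METHOD_CHOICES = ("ivw", "ivw_re", "egger", "weighted_median", "penalized_weighted_median")


def run_simulation_study(
    scenario,
    n_reps: int,
    seed: int = 0,
    methods=METHOD_CHOICES,
    n_boot: int = 200,
) -> pd.DataFrame:
    """Repeat simulate -> estimate ``n_reps`` times and summarize per method.

    ``scenario`` is a :class:`SimulationConfig` or a path to a YAML scenario
    file.  Reports bias, empirical SE, mean estimated SE, 95% CI coverage of
    the true effect, and the rejection rate at nominal 5%.  With
    ``n_reps=1`` the summary holds the single replicate's point values
    (bias = estimate - truth; coverage/rejection are that replicate's 0/1
    outcomes).
    """
    if not isinstance(scenario, SimulationConfig):
        scenario = SimulationConfig.from_yaml(scenario)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for rep in range(n_reps):
        hset, truth = simulate_harmonized(scenario, rng)
        boot = est.BootstrapConfig(n_boot=n_boot, seed=int(rng.integers(2**31)))
        for method in methods:
            if method == "ivw":
                e = est.ivw(hset, "fixed")
            elif method == "ivw_re":
                e = est.ivw(hset, "multiplicative_random")
            elif method == "egger":
                e, _ = est.mr_egger(hset, boot=None)
            elif method == "weighted_median":
                e = est.weighted_median(hset, penalized=False, boot=boot)
            elif method == "penalized_weighted_median":
                e = est.weighted_median(hset, penalized=True, boot=boot)
            else:
                raise ValueError(f"unknown method {method!r}")
            records.append(
                {
                    "rep": rep, "method": method, "estimate": e.beta, "se": e.se,
                    "covered": e.ci_low <= scenario.beta_true <= e.ci_high,
                    "rejected": e.pvalue < 0.05,
                }
            )
    raw = pd.DataFrame(records)
    summary = (
        raw.groupby("method", sort=False)
        .agg(
            bias=("estimate", lambda v: v.mean() - scenario.beta_true),
            empirical_se=("estimate", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            mean_se=("se", "mean"),
            coverage=("covered", "mean"),
            rejection_rate=("rejected", "mean"),
            mean_estimate=("estimate", "mean"),
        )
        .reset_index()
    )
    summary.attrs["raw"] = raw
    summary.attrs["scenario"] = scenario
    return summary
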