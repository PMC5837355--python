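"""Instrument selection and strength: genome-wide filtering, LD pruning,
overlap exclusion, variance explained and power.

Instruments for a two-sample MR analysis are selected at the genome-wide
significance threshold (p < 5e-8), thinned so that no retained pair is in
linkage disequilibrium above an r-squared threshold, and (when two exposures
share variants) shared instruments are excluded so each exposure keeps a
trait-specific set.  Linkage disequilibrium is supplied as data — a pairwise
r-squared list from an external reference panel — not computed from
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Tuple
import warnings

import numpy as np
from scipy import stats

from .sumstats import SummaryDataset

__all__ = [
    "LDInfo",
    "InstrumentSet",
    "filter_genomewide",
    "ld_prune",
    "exclude_overlap",
    "variance_explained",
    "mr_power",
    "read_ld_pairs",
]


class LDInfo:
    """Symmetric pairwise r-squared lookup; unlisted pairs mean r^2 = 0."""

    def __init__(self, pairs: Optional[Mapping[Tuple[str, str], float]] = None):
        self._r2: dict[frozenset, float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 for ({a}, {b}) outside [0, 1]: {r2}")
        key = frozenset((a, b))
        prev = self._r2.get(key)
        if prev is not None and prev != r2:
            raise ValueError(f"conflicting r2 for pair ({a}, {b}): {prev} vs {r2}")
        self._r2[key] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._r2)


def read_ld_pairs(path) -> LDInfo:
    """Read a whitespace-delimited three-column (snp_a, snp_b, r2) file."""
    ld = LDInfo()
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].lower() in ("snp_a", "snpa", "snp1"):
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            ld.set(parts[0], parts[1], float(parts[2]))
    return ld


@dataclass
class InstrumentSet:
    """An ordered set of instrument SNP ids with a per-candidate audit log.

    ``selection_log`` records every candidate exactly once as a
    (snp_id, action, reason) triple, action in {"keep", "drop"}.
    """

    trait_name: str
    snp_ids: list[str]
    selection_log: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.snp_ids)

    def write(self, path, log_path=None) -> None:
        with open(path, "wt") as fh:
            for s in self.snp_ids:
                fh.write(s + "\n")
        if log_path is not None:
            with open(log_path, "wt") as fh:
                fh.write("snp_id\taction\treason\n")
                for snp, action, reason in self.selection_log:
                    fh.write(f"{snp}\t{action}\t{reason}\n")


def filter_genomewide(dataset: SummaryDataset, threshold: float = 5e-8) -> InstrumentSet:
    """Retain SNPs with association p-value strictly below ``threshold``."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    kept, log = [], []
    for rec in dataset.records:
        if rec.pvalue < threshold:
            kept.append(rec.snp_id)
            log.append((rec.snp_id, "keep", f"p={rec.pvalue:.3g} < {threshold:.3g}"))
        else:
            log.append((rec.snp_id, "drop", f"p={rec.pvalue:.3g} >= {threshold:.3g}"))
    if not kept:
        warnings.warn(
            f"{dataset.trait_name}: no SNP below p < {threshold:.3g}", stacklevel=2
        )
    return InstrumentSet(dataset.trait_name, kept, log)


def ld_prune(
    candidates: InstrumentSet,
    dataset: SummaryDataset,
    ld: LDInfo,
    r2_threshold: float = 0.05,
) -> InstrumentSet:
    """Greedy clumping-style pruning at an r-squared threshold.

    Repeatedly keep the unprocessed candidate with the smallest p-value
    (ties broken lexically by snp_id) and remove every remaining candidate
    with r^2 >= ``r2_threshold`` against it.  Deterministic and
    permutation-invariant; the log records which kept SNP caused each
    removal.
    """
    order = sorted(candidates.snp_ids, key=lambda s: (dataset.get(s).pvalue, s))
    kept: list[str] = []
    removed: dict[str, str] = {}
    for snp in order:
        if snp in removed:
            continue
        kept.append(snp)
        for other in order:
            if other == snp or other in removed or other in kept:
                continue
            if ld.r2(snp, other) >= r2_threshold:
                removed[other] = snp
    log = [
        (s, "keep", "index SNP of its LD block")
        if s in kept
        else (s, "drop", f"r2 >= {r2_threshold} with kept SNP {removed[s]}")
        for s in candidates.snp_ids
    ]
    # preserve the candidate ordering for the kept list
    kept_in_order = [s for s in candidates.snp_ids if s in set(kept)]
    return InstrumentSet(candidates.trait_name, kept_in_order, log)


def exclude_overlap(
    set_a: InstrumentSet, set_b: InstrumentSet
) -> tuple[InstrumentSet, InstrumentSet, list[str]]:
    """Remove SNPs shared between two instrument sets from both.

    Used when two correlated exposures (waist- and hip-circumference) draw
    instruments from the same GWAS: shared variants cannot be assigned to
    one exposure and are excluded from both sets.
    """
    shared = sorted(set(set_a.snp_ids) & set(set_b.snp_ids))
    shared_set = set(shared)

    def _reduced(s: InstrumentSet) -> InstrumentSet:
        kept = [x for x in s.snp_ids if x not in shared_set]
        log = [
            (x, "drop", "overlaps the other exposure's instrument set")
            if x in shared_set
            else (x, "keep", "trait-specific instrument")
            for x in s.snp_ids
        ]
        return InstrumentSet(s.trait_name, kept, log)

    return _reduced(set_a), _reduced(set_b), shared


def variance_explained(instruments: InstrumentSet, dataset: SummaryDataset) -> float:
    """Phenotypic variance explained by the instruments on the standardized
    trait scale: R^2 = sum_j 2 * eaf_j * (1 - eaf_j) * beta_j^2, clipped to
    [0, 1].  Requires EAF for every instrument.
    """
    total = 0.0
    for snp in instruments.snp_ids:
        rec = dataset.get(snp)
        if rec.eaf is None:
            raise ValueError(f"missing EAF for instrument {snp}")
        total += 2.0 * rec.eaf * (1.0 - rec.eaf) * rec.beta**2
    return float(np.clip(total, 0.0, 1.0))


def significant_subset(hset, threshold: float = 5e-8):
    """Restrict a harmonized set to SNPs whose exposure association is
    genome-wide significant (two-sided normal p strictly below threshold).

    Instrument sets in practice contain only genome-wide significant SNPs;
    simulated sets must be filtered the same way before orientation-
    sensitive estimators (MR-Egger) are applied, since near-null SNPs can
    have their effect direction mis-estimated.
    """
    p = 2.0 * stats.norm.sf(np.abs(hset.gamma / hset.se_gamma))
    keep = np.where(p < threshold)[0]
    if keep.size == 0:
        raise ValueError("no SNP reaches the significance threshold")
    return hset.subset(keep)


def mr_power(r2: float, n_outcome: int, true_beta: float, alpha: float = 0.05) -> float:
    """Asymptotic two-sided power of the IVW test for standardized traits.

    With z* the (1 - alpha/2) normal quantile and non-centrality
    ncp = |true_beta| * sqrt(n_outcome * r2), returns P(|Z + ncp| > z*).
    Equals alpha when true_beta = 0.
    """
    if not (0 < r2 < 1):
        raise ValueError(f"r2 must be in (0, 1), got {r2}")
    if n_outcome <= 0:
        raise ValueError(f"n_outcome must be positive, got {n_outcome}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    zstar = stats.norm.ppf(1.0 - alpha / 2.0)
    ncp = abs(true_beta) * np.sqrt(n_outcome * r2)
    return float(stats.norm.sf(zstar - ncp) + stats.norm.cdf(-zstar - ncp))
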