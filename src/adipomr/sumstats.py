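"""GWAS summary-statistic tables: reading, writing, validation and allele harmonization.

Two-sample Mendelian randomization combines per-SNP association estimates
from an exposure GWAS (e.g. waist or hip circumference) with estimates from
an outcome GWAS (e.g. log adiponectin).  Before any estimator can run, the
outcome (and any second exposure) betas must be expressed per copy of the
exposure's effect allele.  This module owns the record types, the canonical
file dialect, and the harmonization rules (allele swaps, strand flips,
palindromic-SNP handling).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SNPAssociation",
    "SummaryDataset",
    "HarmonizedSet",
    "SumstatsError",
    "ConfigurationError",
    "EmptyDatasetError",
    "EmptyInstrumentError",
    "read_summary_table",
    "write_summary_table",
    "harmonize",
    "CANONICAL_COLUMNS",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Canonical dialect: tab-delimited, this header, "NA" for missing.
CANONICAL_COLUMNS = {
    "snp_id": "SNP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}


class SumstatsError(Exception):
    """Base class for summary-statistics errors."""


class ConfigurationError(SumstatsError):
    """A required column could not be resolved."""


class EmptyDatasetError(SumstatsError):
    """No valid rows survived validation."""


class EmptyInstrumentError(SumstatsError):
    """Harmonization retained zero SNPs."""


@dataclass(frozen=True)
class SNPAssociation:
    """One variant's summary association with a trait.

    ``beta``/``se`` are on the standardized-trait scale (SD units).  ``eaf``
    is the frequency of ``effect_allele`` and may be missing (None), as may
    the per-SNP sample size ``n``.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pvalue: float
    n: Optional[int] = None

    def validate(self) -> Optional[str]:
        """Return a reason string if any invariant fails, else None."""
        if self.effect_allele not in VALID_ALLELES:
            return f"invalid effect allele {self.effect_allele!r}"
        if self.other_allele not in VALID_ALLELES:
            return f"invalid other allele {self.other_allele!r}"
        if self.effect_allele == self.other_allele:
            return "effect and other allele identical"
        if not math.isfinite(self.beta):
            return "non-finite beta"
        if not (math.isfinite(self.se) and self.se > 0):
            return "nonpositive SE"
        if not (0 < self.pvalue <= 1):
            return "p-value outside (0, 1]"
        if self.eaf is not None and not (0 < self.eaf < 1):
            return "EAF outside (0, 1)"
        if self.n is not None and self.n <= 0:
            return "nonpositive sample size"
        return None

    @property
    def is_palindromic(self) -> bool:
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})

    def flipped(self) -> "SNPAssociation":
        """Record re-expressed per copy of the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            beta=-self.beta,
        )


@dataclass
class SummaryDataset:
    """A validated collection of SNPAssociation records for one trait."""

    trait_name: str
    records: list[SNPAssociation]
    ancestry_label: str = ""
    covariate_adjustments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, SNPAssociation] = {}
        dupes = []
        for rec in self.records:
            if rec.snp_id in seen:
                dupes.append(rec.snp_id)
            else:
                seen[rec.snp_id] = rec
        if dupes:
            warnings.warn(
                f"{self.trait_name}: duplicate snp_id(s) {sorted(set(dupes))}; "
                "keeping first occurrence of each",
                stacklevel=2,
            )
            self.records = list(seen.values())
        self._index = seen

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> SNPAssociation:
        return self._index[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]


def read_summary_table(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_name: Optional[str] = None,
) -> SummaryDataset:
    """Read a delimited GWAS summary table into a validated SummaryDataset.

    Parameters
    ----------
    path
        Tab- or comma-delimited file with a header row.
    column_map
        Mapping from canonical field names (``snp_id``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, ``n``) to
        the file's column names.  Defaults to the canonical dialect header
        (SNP/EA/OA/EAF/BETA/SE/P/N).

    Rows violating record invariants are rejected; each rejection is reported
    in a warning carrying the 0-based data-row index and the reason, and the
    full list is attached as ``dataset.rejected_rows``.
    """
    colmap = dict(CANONICAL_COLUMNS)
    if column_map:
        colmap.update(column_map)
    try:
        # sniff delimiter from the header line
        with open(path, "rt") as fh:
            header = fh.readline()
    except OSError as exc:
        raise SumstatsError(f"cannot read {path}: {exc}") from exc
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA"], keep_default_na=True)

    for fieldname in ("snp_id", "effect_allele", "other_allele", "beta", "se", "pvalue"):
        if colmap[fieldname] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {colmap[fieldname]!r} (field {fieldname}) "
                f"missing from {path}; found {list(df.columns)}"
            )

    records: list[SNPAssociation] = []
    rejected: list[tuple[int, str]] = []
    have_eaf = colmap["eaf"] in df.columns
    have_n = colmap["n"] in df.columns
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))

        def _num(fieldname, cast=float):
            raw = row.get(colmap[fieldname])
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                return None
            return cast(float(raw))

        try:
            rec = SNPAssociation(
                snp_id=str(row[colmap["snp_id"]]).strip(),
                effect_allele=str(row[colmap["effect_allele"]]).strip().upper(),
                other_allele=str(row[colmap["other_allele"]]).strip().upper(),
                eaf=_num("eaf") if have_eaf else None,
                beta=_num("beta"),
                se=_num("se"),
                pvalue=_num("pvalue"),
                n=_num("n", cast=lambda v: int(round(v))) if have_n else None,
            )
        except (TypeError, ValueError) as exc:
            rejected.append((i, f"unparseable row: {exc}"))
            continue
        if rec.beta is None or rec.se is None or rec.pvalue is None:
            rejected.append((i, "missing mandatory numeric field"))
            continue
        reason = rec.validate()
        if reason is not None:
            rejected.append((i, reason))
            continue
        records.append(rec)

    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} row(s): "
            + "; ".join(f"row {i}: {r}" for i, r in rejected[:10]),
            stacklevel=2,
        )
    if not records:
        raise EmptyDatasetError(f"{path}: no valid rows")
    ds = SummaryDataset(
        trait_name=trait_name or str(path), records=records
    )
    ds.rejected_rows = rejected
    return ds


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, int):
        return str(value)
    return repr(float(value))


def write_summary_table(dataset: SummaryDataset, path) -> None:
    """Write a SummaryDataset in the canonical tab-delimited dialect.

    ``read_summary_table`` inverts this bit-exactly (floats are serialized
    via ``repr`` so the round trip preserves every bit).
    """
    cols = list(CANONICAL_COLUMNS.values())
    try:
        with open(path, "wt") as fh:
            fh.write("\t".join(cols) + "\n")
            for r in dataset.records:
                fh.write(
                    "\t".join(
                        [
                            r.snp_id,
                            r.effect_allele,
                            r.other_allele,
                            _fmt(r.eaf),
                            _fmt(r.beta),
                            _fmt(r.se),
                            _fmt(r.pvalue),
                            _fmt(r.n),
                        ]
                    )
                    + "\n"
                )
    except OSError as exc:
        raise SumstatsError(f"cannot write {path}: {exc}") from exc


@dataclass
class HarmonizedSet:
    """Allele-aligned exposure/outcome vectors ready for estimation.

    gamma/se_gamma are the SNP-exposure estimates, Gamma/se_Gamma the
    SNP-outcome estimates, all per copy of the exposure's effect allele.
    gamma2/se_gamma2 hold an optional second exposure (for multivariable
    models).  Every input SNP in the shared id intersection is either
    retained or listed in ``dropped`` with a reason.
    """

    snp_ids: list[str]
    gamma: np.ndarray
    se_gamma: np.ndarray
    Gamma: np.ndarray
    se_Gamma: np.ndarray
    gamma2: Optional[np.ndarray] = None
    se_gamma2: Optional[np.ndarray] = None
    dropped: list[tuple[str, str]] = field(default_factory=list)
    exposure_name: str = "exposure"
    exposure2_name: Optional[str] = None
    outcome_name: str = "outcome"
    eaf: Optional[np.ndarray] = None

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    def subset(self, keep: Sequence[int]) -> "HarmonizedSet":
        """New HarmonizedSet restricted to the given positional indices."""
        keep = np.asarray(keep, dtype=int)
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in keep],
            gamma=self.gamma[keep],
            se_gamma=self.se_gamma[keep],
            Gamma=self.Gamma[keep],
            se_Gamma=self.se_Gamma[keep],
            gamma2=None if self.gamma2 is None else self.gamma2[keep],
            se_gamma2=None if self.se_gamma2 is None else self.se_gamma2[keep],
            dropped=list(self.dropped),
            exposure_name=self.exposure_name,
            exposure2_name=self.exposure2_name,
            outcome_name=self.outcome_name,
            eaf=None if self.eaf is None else self.eaf[keep],
        )

    def swap_roles(self) -> "HarmonizedSet":
        """Exposure and outcome exchanged (for reverse-direction analyses)."""
        return HarmonizedSet(
            snp_ids=list(self.snp_ids),
            gamma=self.Gamma.copy(),
            se_gamma=self.se_Gamma.copy(),
            Gamma=self.gamma.copy(),
            se_Gamma=self.se_gamma.copy(),
            dropped=list(self.dropped),
            exposure_name=self.outcome_name,
            outcome_name=self.exposure_name,
            eaf=None if self.eaf is None else self.eaf.copy(),
        )


def _align(
    exp: SNPAssociation, other: SNPAssociation, window: float
) -> tuple[Optional[SNPAssociation], Optional[str]]:
    """Express ``other`` per copy of ``exp``'s effect allele.

    Returns (aligned record, None) on success or (None, reason) on drop.
    """
    ea, oa = exp.effect_allele, exp.other_allele
    if exp.is_palindromic:
        # strand is unknowable from alleles; orient by allele-frequency
        # agreement, requiring both EAFs to be informatively far from 0.5
        if not other.is_palindromic:
            return None, "irreconcilable alleles"
        if {other.effect_allele, other.other_allele} != {ea, oa}:
            return None, "irreconcilable alleles"
        if exp.eaf is None or other.eaf is None:
            return None, "missing EAF for palindrome"
        lo, hi = 0.5 - window, 0.5 + window
        if lo <= exp.eaf <= hi or lo <= other.eaf <= hi:
            return None, "ambiguous palindrome"
        # allele labels carry no orientation information for a palindrome
        # (each allele is the strand-image of the other); frequencies decide:
        # same side of 0.5 -> same orientation, opposite sides -> flip
        if (exp.eaf < 0.5) == (other.eaf < 0.5):
            return other, None
        return other.flipped(), None

    pair = (other.effect_allele, other.other_allele)
    if pair == (ea, oa):
        return other, None
    if pair == (oa, ea):
        return other.flipped(), None
    # try the opposite strand
    comp = (COMPLEMENT[other.effect_allele], COMPLEMENT[other.other_allele])
    if comp == (ea, oa):
        return other, None
    if comp == (oa, ea):
        return other.flipped(), None
    return None, "irreconcilable alleles"


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    second_exposure: Optional[SummaryDataset] = None,
    palindromic_eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome (and optional second-exposure) betas to the exposure's
    effect alleles over the shared SNP intersection.

    Swapped alleles flip the beta sign and replace eaf by 1-eaf; strand-flip
    complements (A<->T, C<->G) are resolved before comparison; palindromic
    SNPs are oriented by EAF agreement when both EAFs lie outside
    ``[0.5-w, 0.5+w]`` and dropped otherwise.  Every shared SNP is either
    retained or recorded in ``dropped`` with a reason.
    """
    shared = [s for s in exposure.snp_ids if s in outcome]
    if second_exposure is not None:
        shared = [s for s in shared if s in second_exposure]

    ids: list[str] = []
    g, sg, G, sG, g2, sg2, ea = [], [], [], [], [], [], []
    dropped: list[tuple[str, str]] = []
    for snp in shared:
        exp = exposure.get(snp)
        out, reason = _align(exp, outcome.get(snp), palindromic_eaf_window)
        if out is None:
            dropped.append((snp, reason))
            continue
        if second_exposure is not None:
            sec, reason = _align(exp, second_exposure.get(snp), palindromic_eaf_window)
            if sec is None:
                dropped.append((snp, f"second exposure: {reason}"))
                continue
            g2.append(sec.beta)
            sg2.append(sec.se)
        ids.append(snp)
        g.append(exp.beta)
        sg.append(exp.se)
        G.append(out.beta)
        sG.append(out.se)
        ea.append(np.nan if exp.eaf is None else exp.eaf)

    if not ids:
        raise EmptyInstrumentError(
            f"no SNPs retained harmonizing {exposure.trait_name} with "
            f"{outcome.trait_name} ({len(dropped)} dropped)"
        )
    return HarmonizedSet(
        snp_ids=ids,
        gamma=np.asarray(g, dtype=float),
        se_gamma=np.asarray(sg, dtype=float),
        Gamma=np.asarray(G, dtype=float),
        se_Gamma=np.asarray(sG, dtype=float),
        gamma2=np.asarray(g2, dtype=float) if second_exposure is not None else None,
        se_gamma2=np.asarray(sg2, dtype=float) if second_exposure is not None else None,
        dropped=dropped,
        exposure_name=exposure.trait_name,
        exposure2_name=None if second_exposure is None else second_exposure.trait_name,
        outcome_name=outcome.trait_name,
        eaf=np.asarray(ea, dtype=float),
    )


def export_drop_audit(hset: HarmonizedSet, path) -> None:
    """Write the (snp_id, reason) drop log as a two-column tab file."""
    with open(path, "wt") as fh:
        fh.write("snp_id\treason\n")
        for snp, reason in hset.dropped:
            fh.write(f"{snp}\t{reason}\n")
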