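"""Variant table parsing, rarity/in-silico filters and cohort frequencies.

Consumes a TSV of observed variants (one row per patient-variant) annotated
with gnomAD allele frequency, REVEL and AlphaMissense scores.  Annotations
are inputs: nothing here queries live resources.  Frequencies are reported
as numerator/denominator pairs with the denominator being the number of
patients actually screened for the gene in question (the two recruitment
cohorts were screened for different gene sets).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Zygosity",
    "Consequence",
    "AmBin",
    "VariantRecord",
    "CohortRoster",
    "parse_variant_table",
    "filter_by_af",
    "revel_flag",
    "alphamissense_bin",
    "carrier_frequency",
    "variant_recurrence",
    "zygosity_profile",
    "RateSummary",
]


class VariantTableError(ValueError):
    """Malformed variant table or out-of-range annotation."""


class Zygosity(str, Enum):
    HET = "het"
    HOM = "hom"


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class AmBin(str, Enum):
    LIKELY_BENIGN = "likely_benign"
    UNCERTAIN = "uncertain"
    LIKELY_PATHOGENIC = "likely_pathogenic"


@dataclass(frozen=True)
class RateSummary:
    """A count-based rate; ``rate`` is numerator/denominator."""

    numerator: int
    denominator: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise VariantTableError(f"rate {self.label!r}: denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise VariantTableError(
                f"rate {self.label!r}: numerator {self.numerator} outside 0..{self.denominator}"
            )

    @property
    def rate(self) -> float:
        return self.numerator / self.denominator

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def percent(self) -> float:
        from .acmg import round_half_up

        return round_half_up(100.0 * self.numerator / self.denominator, 2)


@dataclass(frozen=True)
class VariantRecord:
    patient_id: str
    gene: str
    transcript: str
    cdna_change: str
    protein_change: str
    zygosity: Zygosity
    consequence: Consequence
    rsid: str | None = None
    gnomad_af: float | None = None
    revel: float | None = None
    alphamissense: float | None = None

    def __post_init__(self) -> None:
        for name in ("gnomad_af", "revel", "alphamissense"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise VariantTableError(
                    f"{self.patient_id} {self.protein_change}: {name}={value} outside [0, 1]"
                )
        if self.consequence is not Consequence.MISSENSE and (
            self.revel is not None or self.alphamissense is not None
        ):
            raise VariantTableError(
                f"{self.patient_id} {self.protein_change}: missense-only scores present "
                f"on a {self.consequence.value} variant"
            )


@dataclass(frozen=True)
class CohortRoster:
    """Which patients were screened for which genes."""

    cohort_id: int
    patients: frozenset[str]
    genes_screened: frozenset[str]


_REQUIRED_COLUMNS = [
    "patient_id",
    "gene",
    "transcript",
    "cdna_change",
    "protein_change",
    "zygosity",
    "consequence",
]
_OPTIONAL_COLUMNS = ["rsid", "gnomad_af", "revel", "alphamissense", "cohort"]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def parse_variant_table(path) -> list[VariantRecord]:
    """Read and validate a variant TSV; errors cite 1-based data line numbers."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing mandatory column(s) {missing}")
    records: list[VariantRecord] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            records.append(
                VariantRecord(
                    patient_id=row["patient_id"],
                    gene=row["gene"],
                    transcript=row["transcript"],
                    cdna_change=row["cdna_change"],
                    protein_change=row["protein_change"],
                    zygosity=Zygosity(row["zygosity"].strip().lower()),
                    consequence=Consequence(row["consequence"].strip().lower()),
                    rsid=row.get("rsid") or None,
                    gnomad_af=_opt_float(row.get("gnomad_af")),
                    revel=_opt_float(row.get("revel")),
                    alphamissense=_opt_float(row.get("alphamissense")),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise VariantTableError(f"{path}: " + "; ".join(errors))
    return records


def filter_by_af(
    records: Sequence[VariantRecord], threshold: float = 0.05
) -> list[VariantRecord]:
    """Keep variants rarer than ``threshold`` in gnomAD (strict ``<``).

    Records with no population frequency (novel variants) are kept: absence
    of a gnomAD entry cannot argue that a variant is common.
    """
    if not 0.0 < threshold <= 1.0:
        raise VariantTableError(f"threshold must be in (0, 1], got {threshold}")
    return [r for r in records if r.gnomad_af is None or r.gnomad_af < threshold]


def revel_flag(score: float | None) -> bool | None:
    """True iff the REVEL meta-score indicates pathogenicity (> 0.5).

    ``None`` (no score, e.g. a non-missense variant) stays ``None``.
    """
    if score is None:
        return None
    if not 0.0 <= score <= 1.0:
        raise VariantTableError(f"REVEL score {score} outside [0, 1]")
    return score > 0.5


def alphamissense_bin(score: float) -> AmBin:
    """AlphaMissense calibrated bins: <0.34 benign-leaning, >=0.564 pathogenic-leaning."""
    if not 0.0 <= score <= 1.0:
        raise VariantTableError(f"AlphaMissense score {score} outside [0, 1]")
    if score < 0.34:
        return AmBin.LIKELY_BENIGN
    if score < 0.564:
        return AmBin.UNCERTAIN
    return AmBin.LIKELY_PATHOGENIC


def _screened_patients(rosters: Iterable[CohortRoster], gene: str) -> set[str]:
    screened: set[str] = set()
    for roster in rosters:
        if gene in roster.genes_screened:
            screened |= set(roster.patients)
    return screened


def carrier_frequency(
    records: Sequence[VariantRecord],
    rosters: Iterable[CohortRoster],
    gene: str,
) -> RateSummary:
    """Fraction of screened patients carrying >=1 surviving variant in ``gene``."""
    rosters = list(rosters)
    screened = _screened_patients(rosters, gene)
    if not screened:
        raise VariantTableError(f"gene {gene!r} was screened in no cohort")
    carriers = {r.patient_id for r in records if r.gene == gene and r.patient_id in screened}
    return RateSummary(len(carriers), len(screened), label=f"{gene} carriers")


def variant_recurrence(
    records: Sequence[VariantRecord],
    rosters: Iterable[CohortRoster],
    protein_change: str,
) -> RateSummary:
    """Distinct carriers of one protein change over patients screened for its gene."""
    if not protein_change:
        raise VariantTableError("protein_change must be non-empty")
    rosters = list(rosters)
    hits = [r for r in records if r.protein_change == protein_change]
    genes = {r.gene for r in hits}
    if len(genes) > 1:
        raise VariantTableError(
            f"protein change {protein_change!r} maps to multiple genes {sorted(genes)}"
        )
    if hits:
        screened = _screened_patients(rosters, hits[0].gene)
    else:
        # unseen change: denominator defaults to the union of all screened patients
        screened = set().union(*(set(r.patients) for r in rosters))
    carriers = {r.patient_id for r in hits if r.patient_id in screened}
    return RateSummary(len(carriers), len(screened), label=protein_change)


def zygosity_profile(
    records: Sequence[VariantRecord], patient_id: str
) -> dict[str, dict[str, object]]:
    """Per-gene hom/het counts and compound-heterozygosity flag for one patient."""
    profile: dict[str, dict[str, object]] = {}
    for rec in records:
        if rec.patient_id != patient_id:
            continue
        entry = profile.setdefault(
            rec.gene, {"hom": 0, "het": 0, "het_changes": set(), "compound_het": False}
        )
        if rec.zygosity is Zygosity.HOM:
            entry["hom"] += 1
        else:
            entry["het"] += 1
            entry["het_changes"].add(rec.protein_change)
    for entry in profile.values():
        entry["compound_het"] = len(entry.pop("het_changes")) >= 2
    return profile
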