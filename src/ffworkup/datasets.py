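"""Packaged study tables: the transcribed variant, MOAT/Ca2+ and cycle data.

Three small text files under ``ffworkup/data`` hold the per-variant table
(with reported pre/post-functional posterior probabilities), the per-patient
MOAT and calcium summaries, and the per-patient-per-arm treatment-cycle
table.  ``fixtures()`` verifies file checksums before returning anything, so
silent fixture corruption surfaces as an error rather than a wrong rate.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .outcomes import Arm, CycleRecord, Outcome
from .variants import CohortRoster, VariantRecord, parse_variant_table

__all__ = [
    "data_path",
    "variant_table",
    "variant_records",
    "rosters",
    "moat_table",
    "cycle_records",
    "fixtures",
    "FixtureIntegrityError",
]


class FixtureIntegrityError(RuntimeError):
    """Packaged data file does not match its recorded checksum."""


def data_path(name: str) -> Path:
    return Path(resources.files("ffworkup").joinpath("data", name))


def verify_checksums() -> None:
    manifest = json.loads(data_path("checksums.json").read_text())
    for name, expected in manifest.items():
        digest = hashlib.sha256(data_path(name).read_bytes()).hexdigest()
        if digest != expected:
            raise FixtureIntegrityError(
                f"{name}: sha256 {digest} != recorded {expected}"
            )


def variant_table() -> pd.DataFrame:
    """Raw variant table incl. reported pre/post posterior columns."""
    return pd.read_csv(data_path("table1_variants.tsv"), sep="\t", keep_default_na=False)


def variant_records() -> list[VariantRecord]:
    return parse_variant_table(data_path("table1_variants.tsv"))


def rosters() -> tuple[CohortRoster, CohortRoster]:
    """Screening rosters: cohort 1 (P1-P28, PLCZ1 only) and cohort 2
    (P29-P55, PLCZ1 + ACTL7A + ACTL9)."""
    cohort1 = CohortRoster(
        cohort_id=1,
        patients=frozenset(f"P{i}" for i in range(1, 29)),
        genes_screened=frozenset({"PLCZ1"}),
    )
    cohort2 = CohortRoster(
        cohort_id=2,
        patients=frozenset(f"P{i}" for i in range(29, 56)),
        genes_screened=frozenset({"PLCZ1", "ACTL7A", "ACTL9"}),
    )
    return cohort1, cohort2


def moat_table() -> pd.DataFrame:
    """Per-patient MOAT counts plus MOCA/HOCA oocyte numbers and mean A x F."""
    return pd.read_csv(data_path("table2_moat_calcium.tsv"), sep="\t")


def cycle_records() -> list[CycleRecord]:
    df = pd.read_csv(data_path("table3_cycles.csv"), keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        outcomes = tuple(
            Outcome(tok) for tok in str(row["outcomes"]).split(";") if tok
        )
        blasts = row["blastocysts"]
        records.append(
            CycleRecord(
                patient_id=row["patient_id"],
                arm=Arm(row["arm"]),
                n_cycles=int(row["n_cycles"]),
                mii=int(row["mii"]),
                two_pn=int(row["two_pn"]),
                blastocysts=None if blasts == "" else int(blasts),
                embryos_transferred=int(row["embryos_transferred"]),
                transfer_day=str(row["transfer_day"]) or None,
                hcg_positive=int(row["hcg_positive"]),
                outcomes=outcomes,
            )
        )
    return records


def fixtures() -> dict[str, object]:
    """All packaged tables, checksum-verified."""
    verify_checksums()
    return {
        "variants": variant_table(),
        "variant_records": variant_records(),
        "rosters": rosters(),
        "moat": moat_table(),
        "cycles": cycle_records(),
    }
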