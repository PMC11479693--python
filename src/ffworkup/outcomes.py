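"""Clinical-outcome statistics: eligibility, MOAT groups, pooled rates and
exact 2x2 comparisons between conventional ICSI and ICSI-AOA cycles, plus
sperm-phenotype rates (acrosome detachment by TEM, ACTL7A immunofluorescence).

Cycle records may be true single cycles or pooled per-patient-per-arm rows
(``n_cycles`` > 1), as printed in per-patient outcome tables; numerators and
denominators add, so pooled and per-cycle representations aggregate
identically.  All rates are kept as exact integer ratios until presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

from scipy import stats

from .variants import RateSummary

__all__ = [
    "Arm",
    "Outcome",
    "CycleRecord",
    "MOATResult",
    "SpermCellAnnotation",
    "RateSummary",
    "eligibility",
    "moat_group",
    "aggregate_rate",
    "fisher_exact_2x2",
    "compare_arms",
    "detachment_call",
    "detachment_rate",
    "if_expression_class",
    "expression_proportion",
    "IFClass",
    "IFThresholds",
]


class CycleError(ValueError):
    """Invalid cycle record or aggregation request."""


class Arm(str, Enum):
    ICSI = "ICSI"
    ICSI_AOA = "ICSI_AOA"


class Outcome(str, Enum):
    LIVE_BIRTH = "LB"
    MISCARRIAGE = "M"
    BIOCHEMICAL = "BP"
    ONGOING = "Ong"
    NEONATAL_DEATH = "ND"


@dataclass(frozen=True)
class CycleRecord:
    patient_id: str
    arm: Arm
    mii: int
    two_pn: int
    n_cycles: int = 1
    blastocysts: int | None = None  # None = no blastocyst culture
    embryos_transferred: int = 0
    transfer_day: str | None = None  # D2 / D3 / D5
    hcg_positive: int = 0
    outcomes: tuple[Outcome, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.mii < 0 or self.two_pn < 0 or self.n_cycles < 1:
            raise CycleError(f"{self.patient_id}: negative counts")
        if self.two_pn > self.mii:
            raise CycleError(f"{self.patient_id}: two_pn {self.two_pn} > mii {self.mii}")
        if self.blastocysts is not None and self.blastocysts > self.two_pn:
            raise CycleError(
                f"{self.patient_id}: blastocysts {self.blastocysts} > two_pn {self.two_pn}"
            )
        # every recorded clinical outcome implies a positive hCG
        if self.hcg_positive < len(self.outcomes):
            raise CycleError(
                f"{self.patient_id}: {len(self.outcomes)} outcomes but only "
                f"{self.hcg_positive} positive hCG"
            )

    @property
    def fertilization(self) -> Fraction:
        if self.mii == 0:
            raise CycleError(f"{self.patient_id}: no MII oocytes")
        return Fraction(self.two_pn, self.mii)

    @property
    def live_births(self) -> int:
        return sum(1 for o in self.outcomes if o is Outcome.LIVE_BIRTH)


@dataclass(frozen=True)
class MOATResult:
    two_cell: int
    mii: int
    group: int

    @property
    def activation_rate(self) -> Fraction:
        return Fraction(self.two_cell, self.mii)


def eligibility(cycles: Sequence[CycleRecord]) -> bool:
    """Study inclusion: >=1 ICSI cycle with >=4 MII and fertilization <= 1/3.

    The 33.33% bound is evaluated as the exact rational 1/3 so that decimal
    rounding of printed rates cannot flip eligibility at the boundary.
    """
    for cyc in cycles:
        if cyc.arm is not Arm.ICSI or cyc.mii < 4:
            continue
        if cyc.fertilization <= Fraction(1, 3):
            return True
    return False


def moat_group(two_cell: int, mii: int) -> MOATResult:
    """Mouse oocyte activation test group: 1 (<=20%), 2 (21-84%), 3 (>=85%)."""
    if mii < 1:
        raise CycleError("MOAT requires >=1 injected MII oocyte")
    if not 0 <= two_cell <= mii:
        raise CycleError(f"two_cell {two_cell} outside 0..{mii}")
    rate = Fraction(two_cell, mii)
    if rate <= Fraction(1, 5):
        group = 1
    elif rate >= Fraction(85, 100):
        group = 3
    else:
        group = 2
    return MOATResult(two_cell=two_cell, mii=mii, group=group)


_RATE_KINDS = ("fertilization", "blastocyst", "hcg_per_cycle", "lb_per_cycle")


def aggregate_rate(cycles: Iterable[CycleRecord], kind: str) -> RateSummary:
    """Pooled numerator/denominator rate over a cycle selection.

    fertilization: sum 2PN / sum MII.  blastocyst: sum blastocysts / sum 2PN,
    restricted to records with blastocyst culture.  hcg_per_cycle and
    lb_per_cycle: events per started cycle.
    """
    if kind not in _RATE_KINDS:
        raise CycleError(f"unknown rate kind {kind!r}; expected one of {_RATE_KINDS}")
    cycles = list(cycles)
    if not cycles:
        raise CycleError("empty cycle selection")
    if kind == "fertilization":
        num = sum(c.two_pn for c in cycles)
        den = sum(c.mii for c in cycles)
    elif kind == "blastocyst":
        cultured = [c for c in cycles if c.blastocysts is not None]
        num = sum(c.blastocysts for c in cultured)
        den = sum(c.two_pn for c in cultured)
    elif kind == "hcg_per_cycle":
        num = sum(c.hcg_positive for c in cycles)
        den = sum(c.n_cycles for c in cycles)
    else:  # lb_per_cycle
        num = sum(c.live_births for c in cycles)
        den = sum(c.n_cycles for c in cycles)
    if den == 0:
        raise CycleError(f"{kind}: zero denominator")
    return RateSummary(num, den, label=kind)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Conditional probability-mass definition: sum of hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed the observed table's (to within 1e-7 relative slack).
    """
    if min(a, b, c, d) < 0:
        raise CycleError("table entries must be non-negative")
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        raise CycleError("both margins must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def compare_arms(cycles: Iterable[CycleRecord], alpha: float = 0.05) -> dict[str, dict]:
    """ICSI vs ICSI-AOA on fertilization, blastocyst, +hCG and live-birth rates."""
    cycles = list(cycles)
    by_arm = {arm: [c for c in cycles if c.arm is arm] for arm in Arm}
    if not by_arm[Arm.ICSI] or not by_arm[Arm.ICSI_AOA]:
        raise CycleError("compare_arms requires cycles in both arms")
    report: dict[str, dict] = {}
    for kind in _RATE_KINDS:
        rates = {}
        for arm in Arm:
            try:
                rates[arm] = aggregate_rate(by_arm[arm], kind)
            except CycleError:
                rates[arm] = None  # e.g. no blastocyst culture in that arm
        if any(r is None for r in rates.values()):
            report[kind] = {
                "icsi": rates[Arm.ICSI],
                "icsi_aoa": rates[Arm.ICSI_AOA],
                "p_value": None,
                "significant": None,
            }
            continue
        r0, r1 = rates[Arm.ICSI], rates[Arm.ICSI_AOA]
        p = fisher_exact_2x2(
            r0.numerator,
            r0.denominator - r0.numerator,
            r1.numerator,
            r1.denominator - r1.numerator,
        )
        report[kind] = {
            "icsi": r0,
            "icsi_aoa": r1,
            "p_value": p,
            "significant": bool(p < alpha),
        }
    return report


# --- sperm phenotype -------------------------------------------------------


@dataclass(frozen=True)
class SpermCellAnnotation:
    cell_id: str
    acrosome_intact: bool
    detachment_fraction: float  # fraction of acrosome length detached
    folded_curved: bool = False
    if_intensity: float | None = None  # mean grey value, AU
    if_background: float | None = None  # AU

    def __post_init__(self) -> None:
        if not 0.0 <= self.detachment_fraction <= 1.0:
            raise CycleError(
                f"{self.cell_id}: detachment_fraction {self.detachment_fraction} outside [0, 1]"
            )


def detachment_call(cell: SpermCellAnnotation) -> bool:
    """Acrosome counted as detached when >=50% of its length is off the
    nuclear envelope, or when folded/curved with >50% detached."""
    if not cell.acrosome_intact:
        raise CycleError(f"{cell.cell_id}: detachment is scored on intact acrosomes only")
    if cell.folded_curved:
        return cell.detachment_fraction > 0.5
    return cell.detachment_fraction >= 0.5


def detachment_rate(
    cells: Sequence[SpermCellAnnotation],
    control_cells: Sequence[SpermCellAnnotation] | None = None,
    min_cells: int = 20,
) -> dict[str, object]:
    """Detachment rate over intact-acrosome cells, with Fisher p vs control."""
    intact = [c for c in cells if c.acrosome_intact]
    if not intact:
        raise CycleError("no intact-acrosome cells")
    flagged = len(intact) < min_cells
    if flagged:
        warnings.warn(
            f"only {len(intact)} intact cells (< {min_cells}); rate computed anyway",
            stacklevel=2,
        )
    detached = sum(detachment_call(c) for c in intact)
    summary = RateSummary(detached, len(intact), label="acrosome detachment")
    result: dict[str, object] = {"rate": summary, "underpowered": flagged}
    if control_cells is not None:
        ctrl_intact = [c for c in control_cells if c.acrosome_intact]
        ctrl_detached = sum(detachment_call(c) for c in ctrl_intact)
        result["control_rate"] = RateSummary(
            ctrl_detached, len(ctrl_intact), label="control detachment"
        )
        result["fisher_p"] = fisher_exact_2x2(
            detached,
            len(intact) - detached,
            ctrl_detached,
            len(ctrl_intact) - ctrl_detached,
        )
    return result


class IFClass(str, Enum):
    INVISIBLE = "invisible"
    WEAK = "weak"
    OBVIOUS = "obvious"


@dataclass(frozen=True)
class IFThresholds:
    """Background-corrected intensity cut-offs (AU) separating the classes."""

    invisible_max: float
    obvious_min: float

    def __post_init__(self) -> None:
        if self.obvious_min <= self.invisible_max:
            raise CycleError("obvious_min must exceed invisible_max")


def if_expression_class(cell: SpermCellAnnotation, thresholds: IFThresholds) -> IFClass:
    """Invisible / weak / obvious call from background-corrected intensity."""
    if cell.if_intensity is None or cell.if_background is None:
        raise CycleError(f"{cell.cell_id}: immunofluorescence intensities absent")
    corrected = max(0.0, cell.if_intensity - cell.if_background)
    if corrected <= thresholds.invisible_max:
        return IFClass.INVISIBLE
    if corrected >= thresholds.obvious_min:
        return IFClass.OBVIOUS
    return IFClass.WEAK


def expression_proportion(
    cells: Sequence[SpermCellAnnotation],
    thresholds: IFThresholds,
    min_cells: int = 50,
) -> dict[str, object]:
    """Fraction of intact cells with any (weak or obvious) expression."""
    intact = [c for c in cells if c.acrosome_intact]
    if not intact:
        raise CycleError("no intact-acrosome cells")
    flagged = len(intact) < min_cells
    if flagged:
        warnings.warn(
            f"only {len(intact)} intact cells (< {min_cells}); proportion computed anyway",
            stacklevel=2,
        )
    expressing = sum(
        if_expression_class(c, thresholds) is not IFClass.INVISIBLE for c in intact
    )
    return {
        "rate": RateSummary(expressing, len(intact), label="ACTL7A expression"),
        "underpowered": flagged,
    }
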