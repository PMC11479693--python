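"""Bayesian point-based ACMG/AMP variant classification.

Evidence criteria (PVS1, PS1-4, PM1-6, PP1-5; BA1, BS1-4, BP1-7) are combined
on the naturally scaled point scale in which a supporting criterion is worth
1 point, moderate 2, strong 4 and very strong 8, with benign evidence counted
negative.  The net point total ``N`` maps to a posterior probability of
pathogenicity through

    posterior = (O * prior) / ((O - 1) * prior + 1),   O = O_vs ** (N / 8)

with ``prior`` = 0.10 and ``O_vs`` = 350 (odds of pathogenicity of one
very-strong criterion).  Categories follow the point bounds >=10 pathogenic,
6..9 likely pathogenic, 0..5 uncertain (VUS), -6..-1 likely benign,
<=-7 benign, with the stand-alone benign criterion BA1 forcing benign
regardless of the remaining evidence.  Variants of uncertain significance are
sub-graded into "temperature" tiers (hot .. ice cold) by their net points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "Direction",
    "Strength",
    "Category",
    "VusTier",
    "EvidenceItem",
    "BayesParams",
    "ClassificationResult",
    "points_of",
    "net_points",
    "posterior_probability",
    "categorize",
    "vus_tier",
    "classify",
    "update_with_functional",
    "invert_posterior",
    "round_half_up",
]


class Direction(str, Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Strength(str, Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Category(str, Enum):
    PATHOGENIC = "P"
    LIKELY_PATHOGENIC = "LP"
    VUS = "VUS"
    LIKELY_BENIGN = "LB"
    BENIGN = "B"


class VusTier(str, Enum):
    HOT = "hot"
    WARM = "warm"
    TEPID = "tepid"
    COOL = "cool"
    COLD = "cold"
    ICE_COLD = "ice_cold"


class EvidenceError(ValueError):
    """Invalid ACMG evidence item or parameter set."""


@dataclass(frozen=True)
class EvidenceItem:
    """One applied ACMG criterion at a (possibly modified) strength.

    The strength is decoupled from the criterion code so that, e.g., PS3
    applied at supporting strength is expressed as
    ``EvidenceItem("PS3", Direction.PATHOGENIC, Strength.SUPPORTING)``.
    """

    criterion_code: str
    direction: Direction
    strength: Strength

    def __post_init__(self) -> None:
        code = self.criterion_code.strip().upper()
        if not code:
            raise EvidenceError("empty criterion code")
        object.__setattr__(self, "criterion_code", code)
        direction = Direction(self.direction)
        strength = Strength(self.strength)
        object.__setattr__(self, "direction", direction)
        object.__setattr__(self, "strength", strength)
        prefix = code[0]
        expected = {Direction.PATHOGENIC: "P", Direction.BENIGN: "B"}[direction]
        if prefix != expected:
            raise EvidenceError(
                f"criterion {code!r} prefix does not match direction {direction.value!r}"
            )
        if strength is Strength.STAND_ALONE and direction is not Direction.BENIGN:
            raise EvidenceError("stand_alone strength is only valid for benign evidence (BA1)")


#: point worth of each strength level (benign evidence is negated)
POINTS_OF_STRENGTH: dict[Strength, int] = {
    Strength.SUPPORTING: 1,
    Strength.MODERATE: 2,
    Strength.STRONG: 4,
    Strength.VERY_STRONG: 8,
}


@dataclass(frozen=True)
class BayesParams:
    prior: float = 0.10
    odds_very_strong: float = 350.0
    point_of_strength: dict[Strength, int] = field(
        default_factory=lambda: dict(POINTS_OF_STRENGTH)
    )
    # category bounds on net points: (lower inclusive, upper inclusive)
    pathogenic_min: int = 10
    likely_pathogenic_min: int = 6
    vus_min: int = 0
    likely_benign_min: int = -6
    # anything <= likely_benign_min - 1 is benign

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise EvidenceError(f"prior must be in (0, 1), got {self.prior}")
        if self.odds_very_strong <= 1.0:
            raise EvidenceError("odds_very_strong must exceed 1")


@dataclass(frozen=True)
class ClassificationResult:
    net_points: int
    posterior: float
    category: Category
    vus_tier: VusTier | None
    evidence_used: tuple[EvidenceItem, ...]

    @property
    def posterior_3dp(self) -> float:
        """Posterior rounded half-up to 3 decimals for presentation."""
        return round_half_up(self.posterior, 3)


def round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def points_of(item: EvidenceItem, params: BayesParams | None = None) -> int:
    """Signed point value of one evidence item (benign negative).

    BA1 (stand-alone benign) has no finite point value; it is handled as a
    category override in :func:`categorize` and contributes 0 here.
    """
    params = params or BayesParams()
    if item.strength is Strength.STAND_ALONE:
        return 0
    try:
        magnitude = params.point_of_strength[item.strength]
    except KeyError as exc:  # pragma: no cover - guarded by Strength enum
        raise EvidenceError(f"unknown strength {item.strength!r}") from exc
    return magnitude if item.direction is Direction.PATHOGENIC else -magnitude


def net_points(evidence: Iterable[EvidenceItem], params: BayesParams | None = None) -> int:
    params = params or BayesParams()
    return sum(points_of(item, params) for item in evidence)


def posterior_probability(n_points: int | float, params: BayesParams | None = None) -> float:
    """Posterior probability of pathogenicity at a net point total."""
    params = params or BayesParams()
    odds = params.odds_very_strong ** (n_points / 8.0)
    prior = params.prior
    return (odds * prior) / ((odds - 1.0) * prior + 1.0)


def _has_stand_alone_benign(evidence: Iterable[EvidenceItem]) -> bool:
    return any(
        item.strength is Strength.STAND_ALONE and item.direction is Direction.BENIGN
        for item in evidence
    )


def categorize(
    n_points: int,
    evidence: Sequence[EvidenceItem] = (),
    params: BayesParams | None = None,
) -> Category:
    params = params or BayesParams()
    if _has_stand_alone_benign(evidence):
        return Category.BENIGN
    if n_points >= params.pathogenic_min:
        return Category.PATHOGENIC
    if n_points >= params.likely_pathogenic_min:
        return Category.LIKELY_PATHOGENIC
    if n_points >= params.vus_min:
        return Category.VUS
    if n_points >= params.likely_benign_min:
        return Category.LIKELY_BENIGN
    return Category.BENIGN


_TIER_OF_POINTS = {
    5: VusTier.HOT,
    4: VusTier.WARM,
    3: VusTier.TEPID,
    2: VusTier.COOL,
    1: VusTier.COLD,
    0: VusTier.ICE_COLD,
}


def vus_tier(n_points: int) -> VusTier:
    """Temperature tier of a VUS from its net points (5=hot .. 0=ice cold)."""
    try:
        return _TIER_OF_POINTS[n_points]
    except KeyError as exc:
        raise EvidenceError(
            f"vus_tier is only defined on the VUS point range 0..5, got {n_points}"
        ) from exc


def classify(
    evidence: Sequence[EvidenceItem],
    params: BayesParams | None = None,
) -> ClassificationResult:
    """Combine evidence into a full classification result."""
    params = params or BayesParams()
    evidence = tuple(evidence)
    n = net_points(evidence, params)
    category = categorize(n, evidence, params)
    tier = vus_tier(n) if category is Category.VUS else None
    return ClassificationResult(
        net_points=n,
        posterior=posterior_probability(n, params),
        category=category,
        vus_tier=tier,
        evidence_used=evidence,
    )


def update_with_functional(
    base: ClassificationResult,
    extra: Sequence[EvidenceItem],
    params: BayesParams | None = None,
) -> ClassificationResult:
    """Re-classify after functional evidence; may move either direction."""
    return classify(tuple(base.evidence_used) + tuple(extra), params)


def invert_posterior(
    posterior: float,
    params: BayesParams | None = None,
    search_range: tuple[int, int] = (-20, 20),
) -> int:
    """Net point total whose posterior is closest to ``posterior``.

    Ties break toward 0.  Used to recover point totals from reported
    posterior probabilities when the underlying criteria are not published.
    """
    if not 0.0 < posterior < 1.0:
        raise EvidenceError(f"posterior must be in (0, 1), got {posterior}")
    params = params or BayesParams()
    lo, hi = search_range
    best = min(
        range(lo, hi + 1),
        key=lambda n: (abs(posterior_probability(n, params) - posterior), abs(n)),
    )
    return best


def classification_with_points(n_points: int, params: BayesParams | None = None) -> ClassificationResult:
    """Classification result for a bare point total (no itemized evidence).

    Convenience for fixtures where only net points are recoverable.
    """
    params = params or BayesParams()
    category = categorize(n_points, (), params)
    tier = vus_tier(n_points) if category is Category.VUS else None
    return ClassificationResult(
        net_points=n_points,
        posterior=posterior_probability(n_points, params),
        category=category,
        vus_tier=tier,
        evidence_used=(),
    )
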