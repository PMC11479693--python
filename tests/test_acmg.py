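"""Bayesian point-based classifier: point algebra, posterior mapping, tiers."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffworkup import acmg
from ffworkup.acmg import (
    BayesParams,
    Category,
    Direction,
    EvidenceError,
    EvidenceItem,
    Strength,
    VusTier,
)

# the eleven distinct posterior probabilities reported across the variant
# table, indexed by the net point total that produces each
GOLDEN_POSTERIORS = {
    0: 0.1,
    1: 0.188,
    2: 0.325,
    3: 0.5,
    4: 0.675,
    5: 0.812,
    6: 0.9,
    7: 0.949,
    9: 0.988,
    10: 0.994,
    11: 0.997,
}


@pytest.mark.parametrize("points,expected", sorted(GOLDEN_POSTERIORS.items()))
def test_posterior_reproduces_reported_values(points, expected):
    assert acmg.round_half_up(acmg.posterior_probability(points), 3) == expected


def test_posterior_at_zero_points_is_the_prior_exactly():
    params = BayesParams(prior=0.37)
    assert acmg.posterior_probability(0, params) == 0.37


def test_posterior_strictly_increasing_and_bounded():
    values = [acmg.posterior_probability(n) for n in range(-15, 16)]
    assert all(0.0 < v < 1.0 for v in values)
    assert all(a < b for a, b in zip(values, values[1:]))


@pytest.mark.parametrize("points", range(-15, 16))
def test_invert_posterior_round_trips_all_point_totals(points):
    assert acmg.invert_posterior(acmg.posterior_probability(points)) == points


def test_invert_posterior_rejects_degenerate_probabilities():
    with pytest.raises(EvidenceError):
        acmg.invert_posterior(0.0)


@pytest.mark.parametrize(
    "code,direction,strength,expected",
    [
        ("PS3", Direction.PATHOGENIC, Strength.STRONG, 4),
        ("PP3", Direction.PATHOGENIC, Strength.SUPPORTING, 1),
        ("PVS1", Direction.PATHOGENIC, Strength.VERY_STRONG, 8),
        ("PM2", Direction.PATHOGENIC, Strength.MODERATE, 2),
        ("BS3", Direction.BENIGN, Strength.STRONG, -4),
    ],
)
def test_points_of_strength_scheme(code, direction, strength, expected):
    assert acmg.points_of(EvidenceItem(code, direction, strength)) == expected


@pytest.mark.parametrize("strength", [s for s in Strength if s is not Strength.STAND_ALONE])
def test_benign_pathogenic_point_symmetry(strength):
    path = acmg.points_of(EvidenceItem("PS1", Direction.PATHOGENIC, strength))
    benign = acmg.points_of(EvidenceItem("BS1", Direction.BENIGN, strength))
    assert benign == -path


def test_net_points_sums_and_empty_is_zero():
    assert acmg.net_points([]) == 0
    ps = EvidenceItem("PS3", Direction.PATHOGENIC, Strength.STRONG)
    pp = EvidenceItem("PP1", Direction.PATHOGENIC, Strength.SUPPORTING)
    pvs = EvidenceItem("PVS1", Direction.PATHOGENIC, Strength.VERY_STRONG)
    bm = EvidenceItem("BS2", Direction.BENIGN, Strength.MODERATE)
    assert acmg.net_points([ps, pp]) == 5
    assert acmg.net_points([pvs, pp, bm]) == 7


@pytest.mark.parametrize(
    "code,direction,strength",
    [
        ("PS3", Direction.BENIGN, Strength.STRONG),  # prefix/direction mismatch
        ("BA1", Direction.PATHOGENIC, Strength.STAND_ALONE),  # stand-alone pathogenic
        ("", Direction.PATHOGENIC, Strength.STRONG),
    ],
)
def test_evidence_validation_rejects_malformed_items(code, direction, strength):
    with pytest.raises(EvidenceError):
        EvidenceItem(code, direction, strength)


@pytest.mark.parametrize(
    "points,expected",
    [
        (11, Category.PATHOGENIC),
        (10, Category.PATHOGENIC),
        (9, Category.LIKELY_PATHOGENIC),
        (6, Category.LIKELY_PATHOGENIC),
        (5, Category.VUS),
        (0, Category.VUS),
        (-1, Category.LIKELY_BENIGN),
        (-6, Category.LIKELY_BENIGN),
        (-7, Category.BENIGN),
    ],
)
def test_category_point_bounds(points, expected):
    assert acmg.categorize(points) is expected


def test_category_is_monotone_in_points():
    order = [Category.BENIGN, Category.LIKELY_BENIGN, Category.VUS,
             Category.LIKELY_PATHOGENIC, Category.PATHOGENIC]
    ranks = [order.index(acmg.categorize(n)) for n in range(-12, 13)]
    assert ranks == sorted(ranks)


def test_stand_alone_benign_forces_benign_category():
    ba1 = EvidenceItem("BA1", Direction.BENIGN, Strength.STAND_ALONE)
    strong_path = [EvidenceItem("PVS1", Direction.PATHOGENIC, Strength.VERY_STRONG)] * 2
    assert acmg.categorize(16, strong_path + [ba1]) is Category.BENIGN


@pytest.mark.parametrize(
    "points,tier",
    [(5, VusTier.HOT), (4, VusTier.WARM), (3, VusTier.TEPID),
     (2, VusTier.COOL), (1, VusTier.COLD), (0, VusTier.ICE_COLD)],
)
def test_vus_temperature_tiers(points, tier):
    assert acmg.vus_tier(points) is tier


def test_vus_tier_outside_vus_range_is_a_contract_violation():
    with pytest.raises(EvidenceError):
        acmg.vus_tier(6)


def test_classify_composes_points_posterior_category_tier():
    res = acmg.classify([])
    assert (res.net_points, res.posterior_3dp, res.category, res.vus_tier) == (
        0, 0.1, Category.VUS, VusTier.ICE_COLD,
    )
    lp6 = acmg.classify(
        [EvidenceItem("PS3", Direction.PATHOGENIC, Strength.STRONG),
         EvidenceItem("PM2", Direction.PATHOGENIC, Strength.MODERATE)]
    )
    assert (lp6.net_points, lp6.posterior_3dp, lp6.category) == (6, 0.9, Category.LIKELY_PATHOGENIC)
    assert lp6.vus_tier is None


@pytest.mark.parametrize(
    "base_points,extra_direction,extra_strength,want_points,want_posterior,want_category",
    [
        # functional support upgrades a hot VUS to likely pathogenic
        (5, Direction.PATHOGENIC, Strength.SUPPORTING, 6, 0.9, Category.LIKELY_PATHOGENIC),
        # strong functional evidence upgrades LP to pathogenic
        (7, Direction.PATHOGENIC, Strength.STRONG, 11, 0.997, Category.PATHOGENIC),
        # benign functional result downgrades a hot VUS to warm
        (5, Direction.BENIGN, Strength.SUPPORTING, 4, 0.675, Category.VUS),
    ],
)
def test_update_with_functional_moves_either_direction(
    base_points, extra_direction, extra_strength, want_points, want_posterior, want_category
):
    from ffworkup.simulate import evidence_for_points

    base = acmg.classify(evidence_for_points(base_points))
    code = "PS3" if extra_direction is Direction.PATHOGENIC else "BS3"
    updated = acmg.update_with_functional(
        base, [EvidenceItem(code, extra_direction, extra_strength)]
    )
    assert updated.net_points == want_points
    assert updated.posterior_3dp == want_posterior
    assert updated.category is want_category


@settings(max_examples=100, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.sampled_from([Strength.SUPPORTING, Strength.MODERATE,
                             Strength.STRONG, Strength.VERY_STRONG]),
            st.booleans(),
        ),
        max_size=8,
    )
)
def test_classify_consistent_with_its_parts(items):
    evidence = [
        EvidenceItem("PS1" if pathogenic else "BS1",
                     Direction.PATHOGENIC if pathogenic else Direction.BENIGN,
                     strength)
        for strength, pathogenic in items
    ]
    res = acmg.classify(evidence)
    assert res.net_points == acmg.net_points(evidence)
    assert res.posterior == acmg.posterior_probability(res.net_points)
    assert res.category is acmg.categorize(res.net_points, evidence)
    assert (res.vus_tier is not None) == (res.category is Category.VUS)
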