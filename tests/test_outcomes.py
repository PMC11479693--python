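"""Eligibility, MOAT groups, pooled clinical rates, exact tests, phenotypes."""

import math
from itertools import product

import pytest

from ffworkup import outcomes
from ffworkup.outcomes import (
    Arm,
    CycleError,
    CycleRecord,
    IFClass,
    IFThresholds,
    Outcome,
    SpermCellAnnotation,
    aggregate_rate,
    compare_arms,
    detachment_call,
    detachment_rate,
    eligibility,
    expression_proportion,
    fisher_exact_2x2,
    if_expression_class,
    moat_group,
)
from ffworkup.simulate import synthetic_sperm_cells


def brute_force_fisher(a, b, c, d):
    """Independent oracle: exact rational enumeration over the
    hypergeometric support with the probability-mass two-sided rule."""
    from fractions import Fraction

    n, row1, col1 = a + b + c + d, a + b, a + c
    total = math.comb(n, col1)
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = {
        k: Fraction(math.comb(row1, k) * math.comb(n - row1, col1 - k), total)
        for k in support
    }
    observed = pmf[a]
    cutoff = observed + observed * Fraction(1, 10**7)
    return float(sum(p for p in pmf.values() if p <= cutoff))


# --- eligibility -----------------------------------------------------------


def cycle(arm, mii, two_pn, **kw):
    return CycleRecord("X", arm, mii=mii, two_pn=two_pn, **kw)


def test_low_fertilization_history_is_eligible(cycles):
    p2 = [c for c in cycles if c.patient_id == "P2"]
    assert eligibility(p2) is True


def test_mii_floor_blocks_eligibility():
    assert eligibility([cycle(Arm.ICSI, 3, 1)]) is False


def test_eligibility_boundary_is_exact_one_third():
    assert eligibility([cycle(Arm.ICSI, 3000, 1000)]) is True  # exactly 1/3
    assert eligibility([cycle(Arm.ICSI, 10000, 3334)]) is False  # 0.3334
    assert eligibility([cycle(Arm.ICSI_AOA, 10, 0)]) is False  # wrong arm


# --- MOAT ------------------------------------------------------------------


@pytest.mark.parametrize(
    "two_cell,mii,group",
    [(5, 26, 1), (20, 24, 2), (17, 19, 3), (1, 5, 1), (26, 31, 2), (28, 32, 3)],
)
def test_moat_groups_from_activation_rate(two_cell, mii, group):
    assert moat_group(two_cell, mii).group == group


def test_moat_group_monotone_in_rate():
    groups = [moat_group(k, 100).group for k in range(101)]
    assert groups == sorted(groups)


def test_moat_boundary_gap_resolves_to_group_two():
    # between the published 84% and 85% bounds
    assert moat_group(169, 200).group == 2  # 84.5%
    assert moat_group(85, 100).group == 3
    assert moat_group(20, 100).group == 1


def test_moat_requires_injected_oocytes():
    with pytest.raises(CycleError):
        moat_group(0, 0)


def test_fixture_moat_groups_match_reported_labels(moat_table):
    """The rule reproduces every reported group; 'hybrid' labels (1-2)
    contain the rule's group as one of their alternatives."""
    rows = moat_table.dropna(subset=["moat_group_label"])
    rows = rows[rows["moat_group_label"].astype(str) != ""]
    assert len(rows) == 19
    for _, row in rows.iterrows():
        got = moat_group(int(row["moat_two_cell"]), int(row["moat_mii"])).group
        assert str(got) in str(row["moat_group_label"]).split("-")


# --- pooled rates ----------------------------------------------------------


@pytest.mark.parametrize(
    "arm,kind,num,den,pct",
    [
        (Arm.ICSI, "fertilization", 56, 498, 11.24),
        (Arm.ICSI_AOA, "fertilization", 199, 322, 61.80),
        (Arm.ICSI_AOA, "blastocyst", 94, 143, 65.73),
        (Arm.ICSI, "hcg_per_cycle", 5, 47, 10.64),
        (Arm.ICSI_AOA, "hcg_per_cycle", 21, 35, 60.00),
        (Arm.ICSI, "lb_per_cycle", 3, 47, 6.38),
        (Arm.ICSI_AOA, "lb_per_cycle", 13, 35, 37.14),
    ],
)
def test_pooled_clinical_rates(cycles, arm, kind, num, den, pct):
    summary = aggregate_rate([c for c in cycles if c.arm is arm], kind)
    assert (summary.numerator, summary.denominator) == (num, den)
    assert summary.percent == pct


def test_pooling_invariance_over_partitions(cycles):
    """Aggregating a partition piecewise sums to aggregating the union."""
    aoa = [c for c in cycles if c.arm is Arm.ICSI_AOA]
    half1, half2 = aoa[:10], aoa[10:]
    for kind in ("fertilization", "hcg_per_cycle", "lb_per_cycle"):
        whole = aggregate_rate(aoa, kind)
        a, b = aggregate_rate(half1, kind), aggregate_rate(half2, kind)
        assert (whole.numerator, whole.denominator) == (
            a.numerator + b.numerator,
            a.denominator + b.denominator,
        )


def test_aggregate_rate_rejects_empty_and_unknown(cycles):
    with pytest.raises(CycleError):
        aggregate_rate([], "fertilization")
    with pytest.raises(CycleError, match="unknown rate kind"):
        aggregate_rate(cycles, "implantation")


def test_cycle_record_invariants():
    with pytest.raises(CycleError):
        CycleRecord("X", Arm.ICSI, mii=5, two_pn=6)
    with pytest.raises(CycleError):
        CycleRecord("X", Arm.ICSI, mii=10, two_pn=5, blastocysts=6)
    with pytest.raises(CycleError):  # outcomes without matching hCG
        CycleRecord("X", Arm.ICSI, mii=10, two_pn=5, hcg_positive=0,
                    outcomes=(Outcome.LIVE_BIRTH,))


# --- Fisher ----------------------------------------------------------------


def test_symmetric_table_gives_p_one():
    assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)


def test_fisher_invariant_under_row_and_column_swaps():
    p = fisher_exact_2x2(5, 42, 21, 14)
    assert fisher_exact_2x2(21, 14, 5, 42) == pytest.approx(p, rel=1e-12)
    assert fisher_exact_2x2(42, 5, 14, 21) == pytest.approx(p, rel=1e-12)


def test_fisher_matches_enumeration_oracle_on_small_tables():
    # spot-check grid here; the exhaustive margin scan runs in acceptance
    for a, b, c, d in product(range(0, 7, 2), repeat=4):
        if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
            continue
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            brute_force_fisher(a, b, c, d), rel=1e-9, abs=1e-12
        )


def test_fisher_rejects_degenerate_margins():
    with pytest.raises(CycleError):
        fisher_exact_2x2(0, 0, 0, 0)


def test_compare_arms_reproduces_reported_significance(cycles):
    report = compare_arms(cycles)
    assert report["fertilization"]["p_value"] < 0.0001
    assert report["hcg_per_cycle"]["p_value"] < 0.0001
    assert report["lb_per_cycle"]["p_value"] == pytest.approx(0.0007, abs=5e-5)
    assert report["lb_per_cycle"]["significant"] is True
    # no blastocyst culture in the ICSI arm: comparison is reported as absent
    assert report["blastocyst"]["p_value"] is None


def test_identical_arms_compare_at_p_one():
    records = [
        CycleRecord("A", Arm.ICSI, mii=10, two_pn=3),
        CycleRecord("A", Arm.ICSI_AOA, mii=10, two_pn=3),
    ]
    report = compare_arms(records)
    assert report["fertilization"]["p_value"] == pytest.approx(1.0)


# --- sperm phenotype -------------------------------------------------------


def cell(frac, folded=False, intact=True):
    return SpermCellAnnotation("c", intact, frac, folded_curved=folded)


@pytest.mark.parametrize(
    "frac,folded,expected",
    [(0.50, False, True), (0.49, False, False), (0.6, True, True), (0.5, True, False)],
)
def test_detachment_rule(frac, folded, expected):
    assert detachment_call(cell(frac, folded)) is expected


def test_detachment_scored_on_intact_acrosomes_only():
    with pytest.raises(CycleError):
        detachment_call(cell(0.9, intact=False))


def test_detachment_rates_reproduce_reported_summaries():
    cells = synthetic_sperm_cells()
    res = detachment_rate(cells["P29"]["tem"], cells["CONTROL"]["tem"])
    assert res["rate"].percent == 89.29
    assert res["control_rate"].percent == 33.33
    assert res["fisher_p"] < 0.0001
    assert res["underpowered"] is False


def test_detachment_rate_warns_below_cell_floor():
    few = [cell(0.9) for _ in range(5)]
    with pytest.warns(UserWarning, match="intact cells"):
        res = detachment_rate(few)
    assert res["underpowered"] is True
    with pytest.raises(CycleError):
        detachment_rate([])


def test_if_expression_classes_and_config_validation():
    th = IFThresholds(invisible_max=10.0, obvious_min=50.0)
    def if_cell(intensity):
        return SpermCellAnnotation("c", True, 0.0, if_intensity=intensity, if_background=5.0)

    assert if_expression_class(if_cell(5.0), th) is IFClass.INVISIBLE  # corrected 0
    assert if_expression_class(if_cell(35.0), th) is IFClass.WEAK  # midway
    assert if_expression_class(if_cell(80.0), th) is IFClass.OBVIOUS
    with pytest.raises(CycleError):
        IFThresholds(invisible_max=50.0, obvious_min=10.0)
    with pytest.raises(CycleError):
        if_expression_class(cell(0.0), th)  # intensities absent


def test_expression_proportions_reproduce_reported_summaries():
    th = IFThresholds(invisible_max=10.0, obvious_min=50.0)
    cells = synthetic_sperm_cells()
    assert expression_proportion(cells["P29"]["if"], th)["rate"].percent == 24.56
    assert expression_proportion(cells["CONTROL"]["if"], th)["rate"].percent == 66.67
    assert expression_proportion(cells["P46"]["if"], th)["rate"].percent == 15.69


def test_expression_proportion_extremes():
    th = IFThresholds(invisible_max=10.0, obvious_min=50.0)
    invisible = [
        SpermCellAnnotation(f"i{k}", True, 0.0, if_intensity=6.0, if_background=5.0)
        for k in range(60)
    ]
    obvious = [
        SpermCellAnnotation(f"o{k}", True, 0.0, if_intensity=90.0, if_background=5.0)
        for k in range(60)
    ]
    assert expression_proportion(invisible, th)["rate"].percent == 0.0
    assert expression_proportion(obvious, th)["rate"].percent == 100.0
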