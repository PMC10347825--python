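"""The published point system: derivation, categorisation, scoring and
risk lookup."""

import itertools
import json
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from eplscore.scoring import (
    FactorCategory,
    PatientRecord,
    PointSystem,
    RiskFactorSpec,
    RiskTable,
    SpecificationError,
    ValidationError,
    build_point_system,
    categorize,
    compute_category_points,
    follow_up_recommendation,
    lookup_risk,
    published_system,
    round_half_away,
    score_cohort,
    score_patient,
    system_from_dict,
    system_to_dict,
)

# the published points column: (factor, category label) -> points
PUBLISHED_POINTS = {
    ("ma", "<30"): -2, ("ma", "30-39"): 0, ("ma", ">=40"): 2,
    ("gsd", "<9.0"): 3, ("gsd", "9.0-12.9"): 2, ("gsd", "13.0-27.0"): 0,
    ("gsd", ">27.0"): -2,
    ("el", "<2.0"): 2, ("el", "2.1-6.3"): 0, ("el", ">6.3"): -1,
    ("ehr", "<100"): 5, ("ehr", "100-130"): 0, ("ehr", ">=130"): -2,
    ("ysd", "<3.00"): 1, ("ysd", "3.00-4.99"): 0, ("ysd", ">=5.00"): 1,
    ("em", "<10.0"): 1, ("em", "10-14.99"): 0, ("em", ">=15.00"): -1,
}

WORKED_EXAMPLE = dict(ma=38, em=8, gsd=10, ysd=2.2, el=2.5, ehr=88)
BASE_EXAMPLE = dict(ma=34.5, em=12.5, gsd=19, ysd=4, el=4.2, ehr=115)


@pytest.mark.parametrize(
    "x,expected",
    [(1.5, 2), (-1.5, -2), (2.5, 3), (-2.5, -3), (1.49, 1), (-1.7, -2),
     (0.0, 0), (0.5, 1), (-0.5, -1), (1.4999999999, 2)],
)
def test_round_half_away(x, expected):
    assert round_half_away(x) == expected


def test_published_point_table(system):
    derived = {
        (f.name, c.label): c.points for f in system.factors for c in f.categories
    }
    assert derived == PUBLISHED_POINTS


def test_published_system_shape(system, risk_table):
    assert system.B == pytest.approx(5 * 0.0920)
    assert len(system.factors) == 6
    assert len(risk_table.rows) == 23
    assert (system.score_min, system.score_max) == (-8, 14)
    for f in system.factors:
        assert f.base_category.points == 0


@pytest.mark.parametrize(
    "factor,value,label",
    [
        ("ma", 38, "30-39"),
        ("ma", 29.5, "<30"),
        ("ma", 40, ">=40"),
        ("ehr", 88, "<100"),
        ("ehr", 0, "<100"),  # absent cardiac activity
        ("ehr", 130, ">=130"),  # explicit >= label wins at its boundary
        ("ehr", 100, "100-130"),
        ("gsd", 27.0, "13.0-27.0"),  # printed upper bound is inclusive
        ("gsd", 27.1, ">27.0"),
        ("el", 6.3, "2.1-6.3"),
        ("el", 6.4, ">6.3"),
        ("el", 0, "<2.0"),  # absent embryo
        ("ysd", 5.0, ">=5.00"),
        ("em", 15.0, ">=15.00"),
    ],
)
def test_categorize_boundaries(system, factor, value, label):
    spec = system.factor(factor)
    idx = categorize(value, spec)
    assert spec.categories[idx].label == label


@pytest.mark.parametrize("bad", [float("nan"), float("inf"), -1.0])
def test_categorize_rejects_invalid_values(system, bad):
    with pytest.raises(ValidationError, match="ehr"):
        categorize(bad, system.factor("ehr"))


class TestCategoryPoints:
    def test_signed_mode(self, system):
        ma = system.factor("ma")
        top = next(c for c in ma.categories if c.label == ">=40")
        assert compute_category_points(ma, top, 0.46) == 2  # round(1.5) -> 2
        ehr = system.factor("ehr")
        low = next(c for c in ehr.categories if c.label == "<100")
        assert compute_category_points(ehr, low, 0.46) == 5  # round(4.8043)

    def test_base_category_is_exactly_zero(self, system):
        for f in system.factors:
            assert compute_category_points(f, f.base_category, 0.46) == 0

    def test_absolute_mode_scores_both_tails_positive(self, system):
        ysd = system.factor("ysd")
        large = next(c for c in ysd.categories if c.label == ">=5.00")
        assert ysd.deviation_mode == "absolute"
        assert compute_category_points(ysd, large, 0.46) == 1
        # under signed mode the same category would score negative
        signed = RiskFactorSpec(
            name="ysd", beta=ysd.beta, deviation_mode="signed",
            categories=tuple(
                FactorCategory(c.label, c.lower, c.upper, c.representative_value, c.is_base)
                for c in ysd.categories
            ),
        )
        assert compute_category_points(signed, signed.categories[-1], 0.46) == -1

    def test_requires_positive_base_constant(self, system):
        f = system.factor("ma")
        with pytest.raises(SpecificationError, match="B"):
            compute_category_points(f, f.categories[0], 0.0)


class TestBuildPointSystem:
    def test_single_base_only_factor_has_zero_range(self):
        spec = RiskFactorSpec(
            name="ma", beta=0.1,
            categories=(FactorCategory("all", -math.inf, math.inf, 30.0, is_base=True),),
        )
        system = build_point_system([spec], B=1.0)
        assert (system.score_min, system.score_max) == (0, 0)

    def test_gap_between_categories_is_rejected(self):
        with pytest.raises(SpecificationError, match="gap"):
            RiskFactorSpec(
                name="ma", beta=0.1,
                categories=(
                    FactorCategory("low", -math.inf, 30.0, 26.0),
                    FactorCategory("high", 35.0, math.inf, 40.0, is_base=True),
                ),
            )

    def test_overlap_is_rejected(self):
        with pytest.raises(SpecificationError, match="overlap"):
            RiskFactorSpec(
                name="ma", beta=0.1,
                categories=(
                    FactorCategory("low", -math.inf, 30.0, 26.0),
                    FactorCategory("high", 25.0, math.inf, 40.0, is_base=True),
                ),
            )

    def test_exactly_one_base_required(self):
        with pytest.raises(SpecificationError, match="base"):
            RiskFactorSpec(
                name="ma", beta=0.1,
                categories=(
                    FactorCategory("low", -math.inf, 30.0, 26.0),
                    FactorCategory("high", 30.0, math.inf, 40.0),
                ),
            )

    def test_empty_spec_list_rejected(self):
        with pytest.raises(SpecificationError):
            build_point_system([], B=1.0)


class TestScorePatient:
    def test_worked_example(self, system):
        result = score_patient(PatientRecord(**WORKED_EXAMPLE), system)
        assert result.total == 9
        assert result.points == {"ma": 0, "em": 1, "gsd": 2, "ysd": 1, "el": 0, "ehr": 5}

    def test_all_base_categories_score_zero(self, system):
        assert score_patient(PatientRecord(**BASE_EXAMPLE), system).total == 0

    def test_maximal_record_reaches_score_max(self, system):
        record = PatientRecord(ma=45, em=8, gsd=6, ysd=2, el=0, ehr=0)
        assert score_patient(record, system).total == 14 == system.score_max

    def test_total_equals_sum_of_breakdown(self, system):
        result = score_patient(PatientRecord(ma=41, em=16, gsd=28, ysd=6, el=7, ehr=135), system)
        assert result.total == sum(result.points.values())
        assert system.score_min <= result.total <= system.score_max

    def test_invariant_to_factor_order(self, system):
        reordered = PointSystem(factors=tuple(reversed(system.factors)), B=system.B)
        record = PatientRecord(**WORKED_EXAMPLE)
        assert score_patient(record, reordered).total == score_patient(record, system).total

    def test_missing_field_named(self, system):
        with pytest.raises(ValidationError, match="ysd"):
            PatientRecord(ma=30, em=12, gsd=18, ysd=None, el=4, ehr=110)

    @pytest.mark.parametrize("field,value", [("gsd", -1), ("ehr", float("nan"))])
    def test_invalid_field_named(self, field, value):
        kwargs = dict(BASE_EXAMPLE)
        kwargs[field] = value
        with pytest.raises(ValidationError, match=field):
            PatientRecord(**kwargs)

    def test_invalid_outcome_label(self):
        with pytest.raises(ValidationError, match="outcome"):
            PatientRecord(**BASE_EXAMPLE, outcome="miscarriage")


def test_score_cohort_matches_per_record_scoring(system):
    import numpy as np
    import pandas as pd

    rng = np.random.default_rng(42)
    n = 300
    cohort = pd.DataFrame(
        {
            "ma": rng.uniform(20, 45, n).round(0),
            "em": rng.uniform(4, 20, n).round(1),
            "gsd": rng.uniform(3, 30, n).round(1),
            "ysd": rng.uniform(0, 8, n).round(2),
            "el": rng.uniform(0, 9, n).round(1),
            "ehr": rng.uniform(0, 180, n).round(0),
        }
    )
    vectorised = score_cohort(cohort, system)
    looped = [
        score_patient(PatientRecord(**row), system).total
        for row in cohort.to_dict("records")
    ]
    assert vectorised.tolist() == looped


def test_exhaustive_enumeration_matches_score_range(system):
    totals = {
        sum(combo)
        for combo in itertools.product(
            *[[c.points for c in f.categories] for f in system.factors]
        )
    }
    assert min(totals) == system.score_min == -8
    assert max(totals) == system.score_max == 14


class TestRiskTable:
    @pytest.mark.parametrize(
        "total,risk", [(9, 70.67), (5, 30.03), (-8, 0.18), (14, 95.42), (0, 4.20)]
    )
    def test_lookup(self, risk_table, total, risk):
        assert lookup_risk(total, risk_table) == pytest.approx(risk)

    @pytest.mark.parametrize("total", [-9, 15])
    def test_out_of_range_reports_bounds(self, risk_table, total):
        with pytest.raises(ValidationError, match=r"\[-8, 14\]"):
            lookup_risk(total, risk_table)

    def test_strictly_increasing(self, risk_table):
        risks = [r for _, r in risk_table.rows]
        assert all(b > a for a, b in zip(risks, risks[1:]))

    def test_non_consecutive_totals_rejected(self):
        with pytest.raises(SpecificationError, match="consecutive"):
            RiskTable(rows=((0, 1.0), (2, 2.0)))

    def test_non_increasing_risk_rejected(self):
        with pytest.raises(SpecificationError, match="increasing"):
            RiskTable(rows=((0, 2.0), (1, 1.0)))


def test_json_round_trip(system, risk_table):
    doc = json.loads(json.dumps(system_to_dict(system, risk_table)))
    rebuilt, table = system_from_dict(doc)
    assert table == risk_table
    assert rebuilt.B == system.B
    for orig, new in zip(system.factors, rebuilt.factors):
        assert orig == new


def test_round_trip_rederives_points_from_betas(system):
    # tampering with a stored points value cannot survive a reload
    doc = system_to_dict(system)
    doc["factors"][0]["categories"][0]["points"] = 99
    rebuilt, _ = system_from_dict(doc)
    assert rebuilt.factors[0].categories[0].points == system.factors[0].categories[0].points


@given(st.integers(min_value=-8, max_value=14))
def test_recommendation_triage(total):
    text = follow_up_recommendation(total)
    if total >= 5:
        assert "7-10 days" in text
    else:
        assert "day 45" in text
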