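import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from rsspa import (
    ConnectionNumber,
    GradeThresholds,
    ValidationError,
    WeightVector,
    assess_panel,
    build_evaluation_matrix,
    coefficient_scheme,
    comprehensive_connection,
    evaluate_connection,
    judge_grade,
    partial_connection,
    set_pair_potential,
    single_index_connection,
)
from rsspa.set_pair import default_thresholds

PM25 = GradeThresholds(35, 75, 115, 150, 250)


def conn_strategy():
    return (
        st.lists(st.floats(0, 1), min_size=5, max_size=5)
        .filter(lambda v: sum(v) > 1e-6)
        .map(lambda v: ConnectionNumber(*(x / sum(v) for x in v)))
    )


class TestSingleIndexConnection:
    def test_below_s1_pure_identity(self):
        assert single_index_connection(20, PM25).components == (1, 0, 0, 0, 0)
        assert single_index_connection(35, PM25).components == (1, 0, 0, 0, 0)

    def test_midpoint_splits_evenly(self):
        cn = single_index_connection(55, PM25)  # midway 35..75
        assert cn.components == pytest.approx((0.5, 0.5, 0, 0, 0))

    def test_hebei_2013_pm25(self):
        # concentration implied by the 2013 PM2.5 sub-index 141.25
        cn = single_index_connection(108, PM25)
        assert cn.components == pytest.approx((0, 0.175, 0.825, 0, 0))

    def test_above_s5_pure_opposition(self):
        assert single_index_connection(300, PM25).components == (0, 0, 0, 0, 1)

    def test_continuous_at_thresholds(self):
        for s in PM25.as_tuple:
            lo = single_index_connection(s - 1e-9, PM25).components
            hi = single_index_connection(s + 1e-9, PM25).components
            assert lo == pytest.approx(hi, abs=1e-6)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(x=st.floats(0, 400))
    def test_conservation_and_monotone_drift(self, x):
        cn = single_index_connection(x, PM25)
        assert sum(cn.components) == pytest.approx(1.0, abs=1e-9)
        # centre of mass over component index grows with x
        com = sum(i * v for i, v in enumerate(cn.components))
        com2 = sum(i * v for i, v in enumerate(single_index_connection(x + 5, PM25).components))
        assert com2 >= com - 1e-9

    def test_invalid_thresholds(self):
        with pytest.raises(ValidationError):
            GradeThresholds(5, 4, 3, 2, 1)


class TestEvaluationMatrix:
    def test_rows_normalised(self):
        rows = build_evaluation_matrix([(3, 1, 0, 0, 0), (4, 0, 0, 0, 0)], z=4)
        assert rows[0] == (0.75, 0.25, 0, 0, 0)
        assert rows[1] == (1, 0, 0, 0, 0)

    def test_uniform_counts(self):
        assert build_evaluation_matrix([(1, 1, 1, 1, 1)], z=5)[0] == (0.2,) * 5

    def test_row_sum_mismatch(self):
        with pytest.raises(ValidationError):
            build_evaluation_matrix([(1, 1, 0, 0, 0)], z=5)


class TestComprehensiveConnection:
    def test_published_2020_and_2014_rows(self, table7):
        for year, expected, tol in (
            (2020, (0.66, 0.2975, 0.0425, 0, 0), 1e-9),
            (2014, (0.328, 0.564, 0.108, 0, 0), 1e-3),
        ):
            sub = table7[table7.year == year]
            conns = [ConnectionNumber(*r) for r in sub[["a", "b1", "b2", "b3", "c"]].values]
            comp = comprehensive_connection(conns)
            assert comp.components == pytest.approx(expected, abs=tol)

    def test_identical_inputs_fixed_point(self):
        cn = ConnectionNumber(0.3, 0.3, 0.2, 0.1, 0.1)
        assert comprehensive_connection([cn] * 4).components == pytest.approx(cn.components)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            comprehensive_connection(
                [ConnectionNumber(1, 0, 0, 0, 0)], WeightVector((0.5, 0.5))
            )


class TestCoefficientScheme:
    def test_equal_proportion_rule(self):
        s = coefficient_scheme()
        assert (s.lambda_, s.gamma, s.phi, s.psi) == (0.5, 0.0, -0.5, -1.0)

    def test_unsupported_grade_count(self):
        with pytest.raises(ValidationError):
            coefficient_scheme(3)


class TestEvaluateConnection:
    def test_extremes(self):
        assert evaluate_connection(ConnectionNumber(1, 0, 0, 0, 0)) == 1
        assert evaluate_connection(ConnectionNumber(0, 0, 0, 0, 1)) == -1
        assert evaluate_connection(ConnectionNumber(0, 0, 1, 0, 0)) == 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(cns=st.lists(conn_strategy(), min_size=2, max_size=5))
    def test_linearity_under_weighted_average(self, cns):
        w = WeightVector.equal(len(cns))
        lhs = evaluate_connection(comprehensive_connection(cns, w))
        rhs = sum(evaluate_connection(c) for c in cns) / len(cns)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(cn=conn_strategy())
    def test_bounded(self, cn):
        assert -1 - 1e-9 <= evaluate_connection(cn) <= 1 + 1e-9


class TestJudgeGrade:
    @pytest.mark.parametrize(
        "degree,grade,level",
        [
            (0.809, "V", "safe"),
            (0.485, "IV", "relatively safe"),
            (-1, "I", "unsafe"),
            (0.6, "V", "safe"),  # boundary goes to the safer grade
            (-0.2, "III", "critical safe"),
            (0.0, "III", "critical safe"),
        ],
    )
    def test_intervals(self, degree, grade, level):
        j = judge_grade(degree)
        assert (j.grade, j.level) == (grade, level)

    def test_monotone(self):
        order = "I II III IV V".split()
        grades = [order.index(judge_grade(-1 + i / 500).grade) for i in range(1001)]
        assert all(b >= a for a, b in zip(grades, grades[1:]))

    def test_out_of_range(self):
        with pytest.raises(ValidationError):
            judge_grade(1.5)


class TestSetPairPotential:
    def test_labels(self):
        assert set_pair_potential(ConnectionNumber(0.4, 0.1, 0.1, 0, 0.4)).label == "balanced"
        assert set_pair_potential(ConnectionNumber(0.5, 0.2, 0.1, 0.1, 0.1)).label == "same"
        assert set_pair_potential(ConnectionNumber(0, 0, 0, 0, 1)).label == "opposite"

    def test_degenerate_c_zero(self):
        same = set_pair_potential(ConnectionNumber(0.76, 0.24, 0, 0, 0))
        assert same.label == "same" and math.isinf(same.ratio)
        indet = set_pair_potential(ConnectionNumber(0, 1, 0, 0, 0))
        assert indet.label == "indeterminate"


class TestPartialConnection:
    def test_pure_identity_is_one_at_every_order(self):
        res = partial_connection(ConnectionNumber(1, 0, 0, 0, 0))
        assert res.order1 == (1, 0, 0, 0)
        assert res.order2[0] == res.order3[0] == res.order4 == 1

    def test_uniform_gives_half_everywhere(self):
        res = partial_connection(ConnectionNumber(0.2, 0.2, 0.2, 0.2, 0.2))
        assert res.order1 == (0.5,) * 4
        assert res.order2 == (0.5,) * 3
        assert res.order4 == 0.5

    def test_against_exact_fraction_oracle(self):
        comps = (Fraction(2, 5), Fraction(3, 10), Fraction(1, 5), Fraction(7, 100),
                 Fraction(3, 100))

        def step(t):
            return tuple(u / (u + v) for u, v in zip(t, t[1:]))

        o1 = step(comps)
        o4 = step(step(step(o1)))
        res = partial_connection(ConnectionNumber(*(float(c) for c in comps)))
        assert res.order1 == pytest.approx(tuple(map(float, o1)))
        assert res.order4 == pytest.approx(float(o4[0]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(cn=conn_strategy())
    def test_entries_in_unit_interval(self, cn):
        res = partial_connection(cn)
        flat = (*res.order1, *res.order2, *res.order3, res.order4)
        assert all(0 <= v <= 1 for v in flat)

    def test_order_validation(self):
        with pytest.raises(ValidationError):
            partial_connection(ConnectionNumber(1, 0, 0, 0, 0), order=5)


class TestAssessPanel:
    def test_safest_single_indicator(self):
        panel = {y: {"PM2.5": 10.0} for y in (2019, 2020)}
        res = assess_panel(panel, {"PM2.5": PM25})
        assert all(r.degree == pytest.approx(1.0) for r in res)
        assert res[0].judgment.grade == "V"
        assert res[0].trend is None and res[1].trend == "steady"

    def test_trend_labels_follow_degree(self):
        panel = {1: {"PM2.5": 120.0}, 2: {"PM2.5": 60.0}, 3: {"PM2.5": 90.0}}
        res = assess_panel(panel, {"PM2.5": PM25})
        assert [r.trend for r in res] == [None, "improve", "decline"]

    def test_default_thresholds_reproduce_2013_pm25(self):
        th = default_thresholds()
        assert th["PM2.5"].as_tuple == (35, 75, 115, 150, 250)
        cn = single_index_connection(108, th["PM2.5"])
        assert cn.components == pytest.approx((0, 0.175, 0.825, 0, 0))

    def test_missing_threshold_raises(self):
        with pytest.raises(ValidationError):
            assess_panel({1: {"PM2.5": 10.0}}, {})
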