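import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosshaz import (SurvivalSample, build_event_table, integrate_step,
                      kaplan_meier, pooled_km_left, tau_rule)
from crosshaz.core import StepCurve

from .conftest import random_sample


class TestSurvivalSample:
    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError, match="positive"):
            SurvivalSample([0.0, 1.0], [1, 1], [1, 2])

    def test_rejects_bad_status(self):
        with pytest.raises(ValueError, match="status"):
            SurvivalSample([1.0, 2.0], [1, 2], [1, 2])

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two group"):
            SurvivalSample([1.0, 2.0], [1, 1], [1, 1])

    def test_arm_accessors_partition_sample(self):
        s = SurvivalSample([1, 2, 3, 4], [1, 0, 1, 0], [2, 1, 2, 1])
        t1, e1 = s.arm(1)
        t2, e2 = s.arm(2)
        assert sorted(np.concatenate([t1, t2])) == [1, 2, 3, 4]
        assert t1.size + t2.size == s.n


class TestEventTable:
    def test_two_subject_counts(self, toy_two_subjects):
        tab = build_event_table(toy_two_subjects)
        np.testing.assert_array_equal(tab.time, [1.0, 2.0])
        np.testing.assert_array_equal(tab.n_risk, [2, 1])
        np.testing.assert_array_equal(tab.n_risk1, [1, 0])
        np.testing.assert_array_equal(tab.d, [1, 1])
        np.testing.assert_array_equal(tab.d1, [1, 0])

    def test_censored_group_contributes_at_risk_only(self):
        s = SurvivalSample([1.0, 2.0, 3.0], [1, 0, 0], [1, 2, 2])
        tab = build_event_table(s)
        assert tab.time.tolist() == [1.0]
        assert tab.d1.tolist() == [1]
        assert tab.n_risk.tolist() == [3]  # censored subjects still at risk

    def test_event_censoring_tie_keeps_censored_at_risk(self):
        # censored subject at t=2 counted in the risk set of the t=2 event
        s = SurvivalSample([1.0, 2.0, 2.0], [1, 1, 0], [1, 1, 2])
        tab = build_event_table(s)
        assert tab.n_risk.tolist() == [3, 2]
        # brute-force risk set at t=2: subjects with observed time >= 2
        assert tab.n_risk[1] == np.sum(s.time >= 2.0)

    def test_no_events_raises(self):
        s = SurvivalSample([1.0, 2.0], [0, 0], [1, 2])
        with pytest.raises(ValueError, match="no events"):
            build_event_table(s)

    def test_invariants_on_random_samples(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            s = random_sample(rng, n_per_arm=30)
            tab = build_event_table(s)
            assert np.all(np.diff(tab.time) > 0)
            np.testing.assert_array_equal(tab.n_risk, tab.n_risk1 + tab.n_risk2)
            np.testing.assert_array_equal(tab.d, tab.d1 + tab.d2)
            assert np.all(tab.d >= 1) and np.all(tab.d <= tab.n_risk)
            assert np.all(np.diff(tab.n_risk) <= 0)
            assert tab.d.sum() == s.status.sum()

    def test_subject_order_irrelevant(self):
        rng = np.random.default_rng(8)
        s = random_sample(rng, n_per_arm=25)
        perm = rng.permutation(s.n)
        s2 = SurvivalSample(s.time[perm], s.status[perm], s.group[perm])
        a, b = build_event_table(s), build_event_table(s2)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.d1, b.d1)
        np.testing.assert_array_equal(a.n_risk1, b.n_risk1)


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.values, [2 / 3, 1 / 3, 0.0])

    def test_single_censored_is_identity(self):
        km = kaplan_meier([5.0], [0])
        assert km(10.0) == 1.0 and km(0.1) == 1.0

    def test_matches_one_minus_ecdf_without_censoring(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1.0, 200)
        km = kaplan_meier(t, np.ones(200))
        grid = np.linspace(0.01, t.max(), 50)
        ecdf = np.searchsorted(np.sort(t), grid, side="right") / t.size
        np.testing.assert_allclose(np.asarray(km(grid)), 1 - ecdf, atol=1e-12)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(4)
        t = rng.exponential(1.0, 100)
        e = rng.integers(0, 2, 100)
        e[0] = 1
        km = kaplan_meier(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = np.asarray(km(km.knots))
        theirs = kmf.survival_function_at_times(km.knots).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)

    def test_monotone_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = random_sample(rng, n_per_arm=20)
            km = kaplan_meier(s.time, s.status)
            assert np.all(np.diff(km.values) <= 1e-12)
            assert np.all((km.values >= 0) & (km.values <= 1))


class TestPooledKmLeft:
    def test_left_limit_is_one_at_first_event(self, toy_two_subjects):
        pk = pooled_km_left(toy_two_subjects)
        assert pk.left_limit(1.0) == 1.0

    def test_four_subject_left_limit(self):
        s = SurvivalSample([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 0], [1, 1, 2, 2])
        pk = pooled_km_left(s)
        assert pk.left_limit(2.0) == pytest.approx(3 / 4)

    def test_piecewise_constant_between_events(self):
        s = SurvivalSample([1.0, 3.0], [1, 1], [1, 2])
        pk = pooled_km_left(s)
        assert pk.left_limit(1.5) == pk.left_limit(2.9) == pytest.approx(0.5)


class TestIntegrateStep:
    def test_hand_example(self):
        c = StepCurve([1.0, 2.0], [0.5, 0.0])
        assert integrate_step(c, 0.0, 1.5) == pytest.approx(1.25)

    def test_empty_interval_and_order_error(self):
        c = StepCurve([1.0], [0.5])
        assert integrate_step(c, 2.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            integrate_step(c, 3.0, 2.0)

    def test_constant_segment(self):
        c = StepCurve([0.5], [0.25])
        assert integrate_step(c, 1.0, 3.0) == pytest.approx(0.25 * 2.0)

    def test_agrees_with_quadrature_on_random_curves(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            knots = np.sort(rng.uniform(0.1, 5.0, 6))
            knots = np.unique(knots)
            vals = np.sort(rng.uniform(0, 1, knots.size))[::-1]
            c = StepCurve(knots, vals)
            a, b = 0.0, float(knots[-1] + 1.0)
            grid = np.union1d(np.linspace(a, b, 5000), knots)
            riemann = np.sum(np.asarray(c(grid[:-1])) * np.diff(grid))
            assert integrate_step(c, a, b) == pytest.approx(riemann, abs=1e-2)
            # exactness: rectangle sum over the true segments
            edges = np.concatenate([[a], knots[(knots > a) & (knots < b)], [b]])
            exact = np.sum(np.asarray(c(edges[:-1])) * np.diff(edges))
            assert integrate_step(c, a, b) == pytest.approx(exact, abs=1e-12)


class TestStepCurveEvaluation:
    @given(st.floats(min_value=0.0, max_value=10.0))
    @settings(deadline=None, max_examples=50)
    def test_right_continuous_and_bounded(self, t):
        c = StepCurve([1.0, 2.0, 4.0], [0.8, 0.5, 0.1])
        v = c(t)
        assert 0.0 <= v <= 1.0
        if t < 1.0:
            assert v == 1.0

    def test_left_limit_equals_previous_segment(self):
        c = StepCurve([1.0, 2.0], [0.6, 0.2])
        assert c.left_limit(2.0) == pytest.approx(0.6)
        assert c(2.0) == pytest.approx(0.2)
        assert c.left_limit(1.0) == 1.0

    def test_rejects_increasing_values(self):
        with pytest.raises(ValueError):
            StepCurve([1.0, 2.0], [0.4, 0.6])


class TestTauRule:
    def test_arithmetic(self):
        assert tau_rule(SurvivalSample([10.0, 20.0], [1, 1], [1, 2])) == pytest.approx(9.0)
        assert tau_rule(SurvivalSample([8.0, 8.0], [0, 1], [1, 2])) == pytest.approx(7.2)

    def test_below_both_arm_maxima(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            s = random_sample(rng, n_per_arm=10)
            tau = tau_rule(s)
            assert tau < s.arm(1)[0].max() and tau < s.arm(2)[0].max()
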