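"""Survival statistics against hand computations and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

import synthtrial as st
from synthtrial.metrics import ConvergenceError

from conftest import random_survival_fixture


class TestKMCurve:
    def test_hand_computed_four_record_fixture(self):
        """times (2,4,4,7), events (1,1,0,1): S = 3/4, 1/2, 0."""
        c = st.km_curve([2, 4, 4, 7], [1, 1, 0, 1])
        assert c.event_times.tolist() == [2, 4, 7]
        assert c.n_at_risk.tolist() == [4, 3, 1]
        assert c.n_events.tolist() == [1, 1, 1]
        assert c.survival.tolist() == [0.75, 0.5, 0.0]

    def test_all_events_distinct_times_gives_empirical_steps(self):
        c = st.km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        assert c.survival.tolist() == [0.75, 0.5, 0.25, 0.0]

    def test_all_censored_is_flat_at_one(self):
        c = st.km_curve([5, 8, 13], [0, 0, 0])
        assert len(c.event_times) == 0
        assert c.survival_at(10.0) == 1.0

    def test_greenwood_variance_formula(self):
        c = st.km_curve([2, 4, 4, 7], [1, 1, 0, 1])
        # S^2 * cumsum(d / (n(n-d))): 0.75^2 * 1/12; 0.5^2 * (1/12 + 1/6)
        assert c.greenwood_var[0] == pytest.approx(0.75**2 / 12)
        assert c.greenwood_var[1] == pytest.approx(0.25 * (1 / 12 + 1 / 6))
        assert c.greenwood_var[2] == 0.0  # S has reached zero

    @given(hs.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_product_limit_invariants(self, seed):
        """S is non-increasing in [0,1], equals the product-limit formula exactly."""
        t, e = random_survival_fixture(np.random.default_rng(seed))
        c = st.km_curve(t, e)
        if len(c.event_times) == 0:
            return
        assert (np.diff(c.event_times) > 0).all()
        assert (np.diff(c.survival) <= 1e-15).all()
        assert c.survival[0] <= 1.0 and (c.survival >= 0.0).all()
        assert (c.greenwood_var >= 0.0).all()
        expected = np.cumprod(1.0 - c.n_events / c.n_at_risk)
        np.testing.assert_allclose(c.survival, expected, rtol=0, atol=0)

    @given(hs.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_empirical_survival_without_censoring(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 20, size=int(rng.integers(5, 40))).astype(float)
        c = st.km_curve(t, np.ones(len(t), int))
        for u, s in zip(c.event_times, c.survival):
            assert s == pytest.approx((t > u).mean())


class TestMedianSurvival:
    def test_median_of_hand_fixture_is_four(self):
        med = st.median_survival(st.km_curve([2, 4, 4, 7], [1, 1, 0, 1]))
        assert med.mst == 4

    def test_median_undefined_when_curve_stays_above_half(self):
        # 2 events among 8 subjects: S stops at 0.75
        t = [3, 5, 10, 10, 10, 10, 10, 10]
        e = [1, 1, 0, 0, 0, 0, 0, 0]
        med = st.median_survival(st.km_curve(t, e))
        assert med.mst is None and med.ci_high is None

    def test_large_sample_ci_covers_closed_form_median(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(200.0, 20_000)
        med = st.median_survival(st.km_curve(t, np.ones(20_000, int)))
        truth = 200 * math.log(2)
        assert med.mst == pytest.approx(truth, rel=0.03)
        assert med.ci_low <= truth <= med.ci_high

    def test_bounds_bracket_the_median(self):
        t, e = random_survival_fixture(np.random.default_rng(11))
        for transform in ("plain", "log", "loglog"):
            med = st.median_survival(st.km_curve(t, e), transform=transform)
            if med.mst is not None:
                if med.ci_low is not None:
                    assert med.ci_low <= med.mst
                if med.ci_high is not None:
                    assert med.mst <= med.ci_high


def efron_partial_loglik(beta, times, events, groups):
    """Subject-level Efron log partial likelihood (independent of the
    aggregated implementation under test)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    ll = 0.0
    for u in np.unique(times[events == 1]):
        dead = (times == u) & (events == 1)
        at_risk = times >= u
        d = dead.sum()
        risk_sum = np.exp(beta * groups[at_risk]).sum()
        dead_sum = np.exp(beta * groups[dead]).sum()
        ll += beta * groups[dead].sum()
        for l in range(d):
            ll -= math.log(risk_sum - (l / d) * dead_sum)
    return ll


class TestCoxHR:
    def test_identical_samples_give_unit_hazard_ratio(self):
        t = [10, 20, 30, 40, 55]
        e = [1, 1, 0, 1, 1]
        assert st.cox_hr((t, e), (t, e)) == pytest.approx(1.0, abs=1e-10)

    def test_label_swap_inverts_hazard_ratio(self):
        rng = np.random.default_rng(3)
        a = random_survival_fixture(rng)
        b = random_survival_fixture(rng)
        assert st.cox_hr(a, b) * st.cox_hr(b, a) == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_search_of_partial_likelihood(self):
        """10-record fixture, distinct times: β̂ equals the brute-force
        maximizer of the subject-level Efron partial likelihood."""
        ta, ea = [12, 25, 33, 47, 60], [1, 1, 1, 0, 1]
        tb, eb = [8, 19, 42, 51, 70], [1, 0, 1, 1, 1]
        hr = st.cox_hr((ta, ea), (tb, eb))
        times = np.r_[ta, tb]
        events = np.r_[ea, eb]
        groups = np.r_[np.zeros(5), np.ones(5)]
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = [efron_partial_loglik(b, times, events, groups) for b in grid]
        coarse = grid[int(np.argmax(lls))]
        fine = np.arange(coarse - 2e-4, coarse + 2e-4, 1e-6)
        lls = [efron_partial_loglik(b, times, events, groups) for b in fine]
        best = fine[int(np.argmax(lls))]
        assert math.log(hr) == pytest.approx(best, abs=1e-6)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            st.cox_hr(([5, 6], [0, 0]), ([7, 8], [0, 0]))

    def test_complete_separation_reported(self):
        # every early death in group 1, all of group 0 censored late
        with pytest.raises(ConvergenceError):
            st.cox_hr(([100, 110, 120], [0, 0, 0]), ([1, 2, 3], [1, 1, 1]))


class TestHRD:
    @pytest.mark.parametrize(
        "hr, expected",
        [(1.0, 1.0), (1.35, 0.65), (0.8, 0.8), (1.2, 0.8), (2.2, -0.2)],
    )
    def test_values(self, hr, expected):
        assert st.hrd(hr) == pytest.approx(expected, abs=1e-15)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            st.hrd(0.0)
        with pytest.raises(ValueError):
            st.hrd(-1.0)

    @given(hs.floats(0.01, 3.0), hs.floats(0.01, 3.0))
    @settings(max_examples=50, deadline=None)
    def test_maximized_at_one_and_monotone_in_distance(self, a, b):
        assert st.hrd(a) <= 1.0
        if abs(a - 1) < abs(b - 1):
            assert st.hrd(a) > st.hrd(b)


class TestLogrank:
    def test_identical_samples_give_zero_statistic(self):
        t = [10, 20, 30, 40]
        e = [1, 0, 1, 1]
        stat, p = st.logrank_test((t, e), (t, e))
        assert stat == 0.0 and p == 1.0

    def test_clearly_separated_samples_reject(self):
        a = (np.arange(1, 51, dtype=float), np.ones(50, int))
        b = (np.arange(200, 250, dtype=float), np.ones(50, int))
        stat, p = st.logrank_test(a, b)
        assert stat > 10 and p < 1e-3

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            st.logrank_test(([5.0], [0]), ([6.0], [0]))


class TestAgainstLifelines:
    """Dual-route check: all three statistics vs an independent toolchain."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_km_cox_logrank_agree(self, seed):
        from lifelines import CoxPHFitter, KaplanMeierFitter
        from lifelines.statistics import logrank_test as ll_logrank
        import pandas as pd

        rng = np.random.default_rng(seed)
        ta, ea = random_survival_fixture(rng)
        tb, eb = random_survival_fixture(rng)

        c = st.km_curve(ta, ea)
        kmf = KaplanMeierFitter().fit(ta, ea)
        np.testing.assert_allclose(
            c.survival, kmf.survival_function_at_times(c.event_times).to_numpy(), atol=1e-6
        )

        hr = st.cox_hr((ta, ea), (tb, eb))
        df = pd.DataFrame(
            {"t": np.r_[ta, tb], "e": np.r_[ea, eb],
             "g": np.r_[np.zeros(len(ta)), np.ones(len(tb))]}
        )
        cph = CoxPHFitter().fit(df, "t", "e", fit_options={"precision": 1e-10})
        # lifelines' own stopping rule limits agreement to ~5e-5 on beta
        assert math.log(hr) == pytest.approx(cph.params_["g"], abs=5e-5)

        stat, p = st.logrank_test((ta, ea), (tb, eb))
        r = ll_logrank(ta, tb, ea, eb)
        assert stat == pytest.approx(r.test_statistic, abs=1e-6)
        assert p == pytest.approx(r.p_value, abs=1e-6)


class TestEvaluatePair:
    def test_reports_all_metrics_and_hr_direction(self, actual_trial):
        gen = st.TreeSynthesizer("cart").fit(actual_trial)
        synth = gen.sample(actual_trial.n, 4242)
        res = st.evaluate_pair(actual_trial, synth, "os")
        assert set(res) >= {"mst", "ci_low", "ci_high", "hr", "hrd", "logrank_p"}
        rev = st.evaluate_pair(actual_trial, synth, "os", hr_direction="actual_vs_synthetic")
        assert res["hr"] * rev["hr"] == pytest.approx(1.0, abs=1e-6)
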