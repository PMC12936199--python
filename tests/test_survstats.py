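"""Survival and association statistics against hand and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import fisher_exact as scipy_fisher_2x2

from ctdna_monitor.survstats import (
    cox_fit,
    fisher_exact_rxc,
    km_estimate,
    logrank_test,
    time_dependent_auc,
)

# 6-subject toy data with tied event times, exercising Efron's correction
TOY_TIMES = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 4.0])
TOY_EVENTS = np.array([1, 1, 1, 0, 1, 1])
TOY_X = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])


def efron_neg_loglik(beta, times, events, x):
    """Efron partial likelihood, written directly from its definition."""
    ll = 0.0
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        risk = times >= t
        d = dead.sum()
        theta_risk = np.exp(beta * x[risk]).sum()
        theta_dead = np.exp(beta * x[dead]).sum()
        ll += beta * x[dead].sum()
        for l in range(d):
            ll -= math.log(theta_risk - (l / d) * theta_dead)
    return -ll


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = km_estimate([5, 10, 15], [0, 0, 0])
        assert km.survival_at(0) == 1.0
        assert km.survival_at(14) == 1.0

    def test_hand_product(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert km.survival_at(2.5) == pytest.approx(1 / 3)  # (2/3)(1/2)
        assert km.survival_at(0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(100, 50)
        km = km_estimate(t, np.ones(50))
        for q in (20.0, 80.0, 200.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean())

    def test_empty_input(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestCox:
    def test_identical_groups_hr_one(self):
        # two groups with the same event pattern: covariate carries no signal
        times = np.tile([2.0, 5.0, 9.0], 2)
        events = np.tile([1, 0, 1], 2)
        x = np.repeat([0.0, 1.0], 3)
        res = cox_fit(pd.DataFrame({"g": x}), times, events)[0]
        assert res.hazard_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.ci_low <= 1.0 <= res.ci_high

    def test_matches_brute_force_efron_oracle(self):
        res = cox_fit(pd.DataFrame({"x": TOY_X}), TOY_TIMES, TOY_EVENTS)[0]
        opt = minimize_scalar(
            efron_neg_loglik, bounds=(-5, 5), method="bounded",
            args=(TOY_TIMES, TOY_EVENTS, TOY_X),
            options={"xatol": 1e-10},
        )
        assert math.log(res.hazard_ratio) == pytest.approx(opt.x, abs=1e-6)

    def test_label_swap_reciprocal(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 2, 60).astype(float)
        t = rng.exponential(100 * (1 + x), 60)
        e = np.ones(60)
        hr = cox_fit(pd.DataFrame({"x": x}), t, e)[0].hazard_ratio
        hr_sw = cox_fit(pd.DataFrame({"x": 1 - x}), t, e)[0].hazard_ratio
        assert hr * hr_sw == pytest.approx(1.0, abs=1e-9)

    def test_parameter_recovery(self):
        # exponential survival at true HR 0.25
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, 500).astype(float)
        lam = 0.01 * 0.25**x
        t = rng.exponential(1 / lam)
        c = rng.uniform(50, 400, 500)
        res = cox_fit(
            pd.DataFrame({"x": x}), np.minimum(t, c), (t <= c).astype(int)
        )[0]
        assert abs(np.log(res.hazard_ratio) - np.log(0.25)) < 0.3 * abs(np.log(0.25))

    def test_rejects_constant_covariate_and_no_events(self):
        with pytest.raises(ValueError):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1, 2, 3], [1, 1, 0])
        with pytest.raises(ValueError):
            cox_fit(pd.DataFrame({"x": [0.0, 1.0]}), [1, 2], [0, 0])

    def test_separation_is_flagged_not_silent(self):
        # perfectly separated groups: monotone likelihood
        times = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.ones(6, dtype=int)
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        res = cox_fit(pd.DataFrame({"x": x}), times, events)[0]
        assert res.flagged


class TestLogrank:
    def test_identical_groups(self):
        t = [3.0, 5.0, 8.0] * 2
        e = [1, 0, 1] * 2
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_computed_toy(self):
        # groups A: events at 1, 3; B: events at 2, 4 (all events)
        t = np.array([1.0, 3.0, 2.0, 4.0])
        e = np.ones(4, dtype=int)
        g = np.array([0, 0, 1, 1])
        # O-E for A: (1-2/4) + (1-1/3) + (0-1/2) = 2/3; V = 1/4+2/9+1/4 = 13/18
        stat = (2 / 3) ** 2 / (13 / 18)
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(stat, rel=1e-9)

    def test_group_swap_invariance(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(50, 30)
        e = rng.integers(0, 2, 30)
        g = rng.integers(0, 2, 30)
        if len(np.unique(g)) < 2:
            g[0] = 1 - g[0]
        a = logrank_test(t, e, g)
        b = logrank_test(t, e, 1 - g)
        assert a.statistic == pytest.approx(b.statistic)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestFreemanHalton:
    def test_two_by_two_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tab = rng.integers(0, 15, (2, 2))
            if tab.sum() == 0:
                continue
            expected = scipy_fisher_2x2(tab)[1]
            assert fisher_exact_rxc(tab) == pytest.approx(expected, rel=1e-9)

    def test_zero_margin_single_table(self):
        assert fisher_exact_rxc([[0, 0, 0], [1, 2, 3]]) == 1.0
        assert fisher_exact_rxc([[5, 0], [3, 0]]) == 1.0

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            tab = rng.integers(0, 10, (2, 3))
            if tab.sum(0).min() == 0 or tab.sum(1).min() == 0:
                continue
            p = fisher_exact_rxc(tab)
            assert 0 < p <= 1

    def test_bad_input(self):
        with pytest.raises(ValueError):
            fisher_exact_rxc([[-1, 2], [3, 4]])
        with pytest.raises(ValueError):
            fisher_exact_rxc(np.ones((2, 2), dtype=int) * 200)


class TestTimeDependentAuc:
    def test_perfect_marker_no_censoring(self):
        t = np.array([10.0, 20, 30, 100, 120, 140])
        e = np.ones(6, dtype=int)
        marker = np.array([3.0, 2.9, 2.8, 0.1, 0.2, 0.3])
        assert time_dependent_auc(marker, t, e, horizon=50) == pytest.approx(1.0)

    def test_random_marker_near_half(self):
        rng = np.random.default_rng(6)
        n = 1000
        t = rng.exponential(100, n)
        marker = rng.normal(size=n)
        auc = time_dependent_auc(marker, t, np.ones(n, dtype=int), horizon=80)
        se = 3 / np.sqrt(n)  # generous bound on 3 SE of an AUC near 0.5
        assert abs(auc - 0.5) < se

    def test_no_censoring_equals_empirical_rank_auc(self):
        rng = np.random.default_rng(8)
        n = 200
        marker = rng.normal(size=n)
        t = rng.exponential(50 * np.exp(-0.5 * marker))
        e = np.ones(n, dtype=int)
        horizon = 40.0
        case = t <= horizon
        # empirical AUC: P(marker_case > marker_control) + 0.5 ties
        mc, mn = marker[case], marker[~case]
        gt = (mc[:, None] > mn[None, :]).mean()
        eq = (mc[:, None] == mn[None, :]).mean()
        assert time_dependent_auc(marker, t, e, horizon) == pytest.approx(gt + 0.5 * eq, abs=1e-9)

    def test_undefined_without_cases(self):
        with pytest.raises(ValueError):
            time_dependent_auc([1.0, 2.0], [100.0, 120.0], [1, 1], horizon=50)
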