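"""Survival stage against brute-force product-limit and score-test oracles."""

import numpy as np
import pandas as pd
import pytest

from cvhrisk.survival import (
    CoxConvergenceError,
    cox_fit,
    km_estimate,
    logrank_test,
    pearson_r,
    threshold_mortality_scan,
)


def brute_force_km(times, events):
    """Product-limit over risk sets, enumerated directly."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    out = {}
    s = 1.0
    for t in np.unique(times[events]):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & events)
        s *= 1.0 - d / n_at_risk
        out[t] = s
    return out


def brute_force_logrank_2group(group, times, events):
    """Two-group log-rank statistic: sum over event times of O-E and V."""
    group = np.asarray(group)
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & events).sum()
        d1 = ((times == t) & events & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_three_subject_hand_example(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, True, False])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(2.0) == pytest.approx(1 / 3)

    def test_single_subject_event(self):
        curve = km_estimate([1.0], [True])
        assert curve.survival_at(1.0) == 0.0

    def test_no_events_survival_stays_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [False, False, False])
        assert curve.survival_at(3.0) == 1.0

    def test_matches_brute_force_on_untied_data(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(3.0, 40)
        events = rng.uniform(size=40) < 0.7
        curve = km_estimate(times, events)
        for t, s in brute_force_km(times, events).items():
            assert curve.survival_at(t) == pytest.approx(s, rel=1e-12)

    def test_ci_brackets_estimate_and_stays_in_unit_interval(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(3.0, 200).clip(max=5.0)
        events = (times < 5.0) & (rng.uniform(size=200) < 0.9)
        curve = km_estimate(times, events)
        assert np.all(curve.ci_low <= curve.survival + 1e-12)
        assert np.all(curve.survival <= curve.ci_high + 1e-12)
        assert np.all((curve.ci_low >= 0) & (curve.ci_high <= 1))
        assert np.all(np.diff(curve.survival) <= 1e-12)

    def test_positive_times_required(self):
        with pytest.raises(ValueError):
            km_estimate([0.0, 1.0], [True, True])


class TestLogrank:
    def test_identical_groups_give_zero(self):
        times = np.r_[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = np.r_[True, True, False, True, True, False]
        group = np.r_[0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(group, times, events)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_toy_example_matches_risk_set_enumeration(self):
        times = np.array([1.0, 2.0, 4.0, 1.5, 3.0, 5.0])
        events = np.array([True, True, True, True, False, True])
        group = np.array([0, 0, 0, 1, 1, 1])
        chi2, _ = logrank_test(group, times, events)
        assert chi2 == pytest.approx(brute_force_logrank_2group(group, times, events), rel=1e-9)

    def test_separated_exponential_groups_significant(self):
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            t0 = rng.exponential(4.0, 200)
            t1 = rng.exponential(1.0, 200)
            times = np.r_[t0, t1]
            events = np.ones(400, bool)
            group = np.r_[np.zeros(200, int), np.ones(200, int)]
            _, p = logrank_test(group, times, events)
            hits += p < 0.001
        assert hits >= int(0.99 * n_seeds)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([0, 0, 0], [1.0, 2.0, 3.0], [True, True, True])


class TestCoxFit:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(100)
        n = 500
        x = (rng.uniform(size=n) < 0.5).astype(float)
        times = rng.exponential(2.0, n)
        fit = cox_fit(pd.DataFrame({"x": x}), times, np.ones(n, bool))
        lo, hi = fit.ci95("x")
        assert lo < 1.0 < hi

    def test_recovers_rate_ratio_two_at_n_2000(self):
        rng = np.random.default_rng(42)
        n = 2000
        x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        times = rng.exponential(np.where(x == 1, 0.5, 1.0))
        fit = cox_fit(pd.DataFrame({"x": x}), times, np.ones(n, bool))
        assert 1.8 <= fit.hazard_ratio("x") <= 2.2

    def test_score_relation_to_logrank_on_untied_data(self):
        # with a single binary covariate the Cox score test at beta=0 is the
        # log-rank statistic; Wald and log-rank then agree closely at large n
        rng = np.random.default_rng(7)
        n = 1000
        x = (rng.uniform(size=n) < 0.5).astype(int)
        times = rng.exponential(np.where(x == 1, 0.7, 1.0))
        events = np.ones(n, bool)
        chi2, p_lr = logrank_test(x, times, events)
        assert chi2 == pytest.approx(brute_force_logrank_2group(x, times, events), rel=1e-9)
        fit = cox_fit(pd.DataFrame({"x": x.astype(float)}), times, events)
        wald_chi2 = (np.log(fit.hazard_ratio("x")) / fit.summary.loc["x", "se"]) ** 2
        assert wald_chi2 == pytest.approx(chi2, rel=0.1)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(
                pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]}),
                [1.0, 2.0, 3.0, 4.0],
                [True, True, True, False],
            )

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="too few events"):
            cox_fit(
                pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]}),
                [1.0, 2.0, 3.0, 4.0],
                [True, False, False, False],
            )


class TestThresholdScan:
    def test_constant_cvhr_gives_single_point(self):
        rng = np.random.default_rng(2)
        n = 100
        cvhr = np.full(n, 50.0)
        times = rng.exponential(4.0, n).clip(max=5.0)
        events = times < 5.0
        scan = threshold_mortality_scan(cvhr, times, events)
        assert len(scan) == 1
        assert scan.iloc[0]["n"] == n

    def test_null_association_curve_flat_within_ci(self):
        rng = np.random.default_rng(3)
        n = 600
        cvhr = rng.uniform(0, 200, n)
        times = rng.exponential(10.0, n).clip(max=5.0)
        events = times < 5.0
        scan = threshold_mortality_scan(cvhr, times, events, thresholds=np.arange(30, 200, 10))
        overall = scan.iloc[-1]["mortality"]
        assert np.all(scan["ci_low"] <= overall + 1e-9)
        assert np.all(overall <= scan["ci_high"] + 1e-9)

    def test_planted_low_cvhr_hazard_gives_decreasing_curve(self):
        rng = np.random.default_rng(4)
        n = 2000
        cvhr = rng.uniform(0, 200, n)
        rate = np.where(cvhr < 60, 0.08, 0.02)  # low CVHR doubles-plus the hazard
        raw = rng.exponential(1.0 / rate)
        times = raw.clip(max=5.0)
        events = raw < 5.0
        scan = threshold_mortality_scan(cvhr, times, events, thresholds=np.array([60.0, 200.0]))
        assert scan.iloc[0]["mortality"] > scan.iloc[1]["mortality"]

    def test_small_subgroups_suppressed(self):
        scan = threshold_mortality_scan(
            np.arange(10.0), np.ones(10) * 2, np.ones(10, bool), min_subgroup=20
        )
        assert scan.empty


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_null_pairs_small_correlation(self):
        small = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x, y = rng.standard_normal((2, 1513))
            small += abs(pearson_r(x, y)) < 0.07
        assert small >= int(0.90 * n_seeds)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r(np.ones(5), np.arange(5.0))
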