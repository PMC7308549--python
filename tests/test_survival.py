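"""Kaplan–Meier, log-rank, Cox PH, cutpoint scan, pruning, LOO selection."""

import numpy as np
import pandas as pd
import pytest

from hexiht import (
    ConfigError,
    UndefinedIndicatorError,
    benjamini_hochberg,
    cox_fit,
    km_estimate,
    logrank_test,
    loo_subset_frequency,
    optimal_cutoff,
    prune_correlated,
    stratify_pr_groups,
)


def logrank_2group_oracle(times, events, group):
    """Independently coded 2-group log-rank chi-square (O-E / variance form)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestKaplanMeier:
    def test_hand_product_limit(self):
        # times (1,2,3), events (1,0,1): S = 2/3 after t=1, 0 after t=3
        km = km_estimate([1, 2, 3], [1, 0, 1])
        assert km.survival_at(1) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3) == pytest.approx(0.0)

    def test_no_censoring_reduces_to_empirical_survival(self, rng):
        t = rng.exponential(10, 200) + 0.01
        km = km_estimate(t, np.ones(200, int))
        for q in (5.0, 10.0, 20.0):
            assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_all_censored_survival_stays_one(self):
        km = km_estimate([5, 10, 15], [0, 0, 0])
        assert km.survival_at(15) == 1.0

    def test_non_positive_times_rejected(self):
        with pytest.raises(ConfigError):
            km_estimate([0.0, 5.0], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [2, 4, 6, 8, 10]
        e = [1, 0, 1, 1, 0]
        stat, p = logrank_test([0] * 5 + [1] * 5, t + t, e + e)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ConfigError):
            logrank_test([1, 1, 1], [1, 2, 3], [1, 1, 1])

    def test_agrees_with_independent_variance_formula(self, rng):
        for _ in range(10):
            n = 40
            t = rng.exponential(10, n) + 0.01
            e = (rng.random(n) < 0.7).astype(int)
            g = (rng.random(n) < 0.5).astype(int)
            if g.sum() in (0, n) or e.sum() == 0:
                continue
            stat, _ = logrank_test(g, t, e)
            assert stat == pytest.approx(logrank_2group_oracle(t, e, g), rel=1e-6)

    def test_null_type_one_error_near_nominal(self, rng):
        # smaller replicate of the calibration check (full run in acceptance)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            t = rng.exponential(20, 60) + 1e-9
            e = (t < 30).astype(int)
            t = np.minimum(t, 30)
            g = (rng.random(60) < 0.5).astype(int)
            if g.sum() in (0, 60):
                continue
            _, p = logrank_test(g, t, e)
            rejections += p < 0.05
        assert rejections / n_sim == pytest.approx(0.05, abs=0.035)


class TestCox:
    def _cohort(self, beta, n, rng):
        x = (rng.random(n) < 0.5).astype(float)
        t = -np.log(rng.random(n)) / (0.05 * np.exp(beta * x))
        e = (t <= 60).astype(int)
        return pd.DataFrame({"time_months": np.minimum(t, 60), "event": e, "x": x})

    def test_null_covariate_beta_near_zero(self, rng):
        m = cox_fit(self._cohort(0.0, 1000, rng), ["x"])
        assert abs(m.coef("x")) < 0.1

    def test_planted_log_hr_recovered(self, rng):
        m = cox_fit(self._cohort(np.log(2), 1000, rng), ["x"])
        assert m.coef("x") == pytest.approx(np.log(2), abs=0.15)
        assert m.summary.loc["x", "hr_lower"] < m.hazard_ratio("x") < m.summary.loc["x", "hr_upper"]

    def test_duplicating_records_keeps_beta_doubles_lr(self, rng):
        df = self._cohort(np.log(2), 300, rng)
        m1 = cox_fit(df, ["x"])
        m2 = cox_fit(pd.concat([df, df], ignore_index=True), ["x"])
        # Efron tie handling perturbs the duplicated-data fit very slightly
        assert m2.coef("x") == pytest.approx(m1.coef("x"), abs=0.01)
        assert m2.lr_statistic == pytest.approx(2 * m1.lr_statistic, rel=0.05)

    def test_constant_covariate_rejected(self, rng):
        df = self._cohort(0.0, 50, rng)
        df["c"] = 1.0
        with pytest.raises(ConfigError, match="'c'"):
            cox_fit(df, ["c"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0], "event": [0, 0],
                           "x": [0.0, 1.0]})
        with pytest.raises(ConfigError, match="event"):
            cox_fit(df, ["x"])


class TestOptimalCutoff:
    def test_perfect_separator_found_in_gap(self, rng):
        # values < 5 die early, values > 5 survive long
        n = 40
        values = np.r_[rng.uniform(0, 4, n // 2), rng.uniform(6, 10, n // 2)]
        times = np.r_[rng.uniform(1, 10, n // 2), rng.uniform(50, 100, n // 2)]
        events = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        res = optimal_cutoff(values, times, events)
        assert 4 <= res.cutoff <= 6

    def test_equals_brute_force_exhaustive_scan(self, rng):
        from lifelines.statistics import multivariate_logrank_test

        for _ in range(10):
            n = 30
            values = rng.normal(0, 1, n)
            times = rng.exponential(20, n) + 0.01
            events = (rng.random(n) < 0.7).astype(int)
            res = optimal_cutoff(values, times, events, min_group_fraction=0.1)
            uniq = np.sort(np.unique(values))
            best_p = None
            min_size = int(np.ceil(0.1 * n))
            for cut in (uniq[:-1] + uniq[1:]) / 2:
                high = values > cut
                if high.sum() < min_size or (~high).sum() < min_size:
                    continue
                p = multivariate_logrank_test(times, high.astype(int), events).p_value
                if best_p is None or p < best_p:
                    best_p = p
            assert res.logrank_p == pytest.approx(best_p)

    def test_constant_indicator_undefined(self, rng):
        with pytest.raises(UndefinedIndicatorError) as err:
            optimal_cutoff(np.ones(20), rng.exponential(10, 20) + 0.01,
                           np.ones(20, int))
        assert err.value.reason == "no_admissible_split"

    def test_min_group_fraction_respected(self, rng):
        res = optimal_cutoff(rng.normal(0, 1, 50), rng.exponential(10, 50) + 0.01,
                             np.ones(50, int), min_group_fraction=0.2)
        assert res.n_low >= 10 and res.n_high >= 10
        assert res.selection_biased


class TestPruneCorrelated:
    def test_duplicated_column_one_survives(self, rng):
        x = rng.normal(0, 1, 100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 100)})
        assert prune_correlated(df) == ["a", "c"]

    def test_independent_columns_both_survive(self, rng):
        df = pd.DataFrame({"a": rng.normal(0, 1, 100), "b": rng.normal(0, 1, 100)})
        assert prune_correlated(df) == ["a", "b"]

    def test_chain_with_priority_keeps_first_and_last(self, rng):
        # A~B r≈0.95, B~C r≈0.95, A~C r≈0.85: greedy keeps A, drops B, keeps C
        cov = np.array([[1.0, 0.95, 0.85], [0.95, 1.0, 0.95], [0.85, 0.95, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), cov, size=5000)
        df = pd.DataFrame(X, columns=["A", "B", "C"])
        corr = df.corr().abs()
        assert corr.loc["A", "B"] > 0.9 and corr.loc["B", "C"] > 0.9
        assert corr.loc["A", "C"] < 0.9
        assert prune_correlated(df, priority=["A", "B", "C"]) == ["A", "C"]


class TestLooSubsetFrequency:
    def test_planted_covariate_dominates_folds(self, rng):
        n = 40
        x = rng.normal(0, 1, n)
        noise1 = rng.normal(0, 1, n)
        noise2 = rng.normal(0, 1, n)
        t = -np.log(rng.random(n)) / (0.05 * np.exp(1.0 * x))
        df = pd.DataFrame({"time_months": np.minimum(t, 60) + 1e-9,
                           "event": (t <= 60).astype(int),
                           "x": x, "n1": noise1, "n2": noise2})
        table = loo_subset_frequency(df, ["x", "n1", "n2"])
        top = table.iloc[0]
        assert "x" in top["subset"]
        assert top["frequency"] > 0.5
        assert table["n_folds"].sum() + table.attrs["n_skipped"] == n

    def test_all_noise_modal_subset_empty(self, rng):
        n = 30
        t = rng.exponential(20, n) + 0.01
        df = pd.DataFrame({"time_months": np.minimum(t, 30),
                           "event": (t <= 30).astype(int),
                           "n1": rng.normal(0, 1, n), "n2": rng.normal(0, 1, n)})
        table = loo_subset_frequency(df, ["n1", "n2"])
        assert table.iloc[0]["subset"] == ()

    def test_small_n_rejected(self, rng):
        df = pd.DataFrame({"time_months": [1.0] * 5, "event": [1] * 5,
                           "x": range(5)})
        with pytest.raises(ConfigError):
            loo_subset_frequency(df, ["x"])


class TestStratifyPr:
    @pytest.mark.parametrize(
        "value,label",
        [(19.9, "low"), (20.0, "moderate"), (50.0, "moderate"),
         (80.0, "moderate"), (80.1, "high"), (0.0, "low"), (100.0, "high")],
    )
    def test_boundaries(self, value, label):
        assert stratify_pr_groups([value])[0] == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            stratify_pr_groups([101.0])


def test_benjamini_hochberg_monotone():
    p = [0.001, 0.01, 0.02, 0.8]
    adj = benjamini_hochberg(p)
    assert (np.diff(adj) >= -1e-12).all()
    assert (adj >= np.asarray(p) - 1e-12).all()
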