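import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cinpipe.stats import (
    SurvivalData,
    c_index,
    cox_fit,
    fisher_exact,
    km_estimate,
    logrank_test,
    logrank_z,
    lrt_nested,
    mann_whitney,
    nri,
    pearson_chi2,
    ph_test,
    roc_cutoff,
    t_test,
    td_roc,
)


def sim_survival(rng, n=200, rate=0.02, hr=1.0, frac=0.5, censor=60.0):
    x = (rng.random(n) < frac).astype(float)
    t = rng.exponential(1.0 / (rate * np.exp(np.log(hr) * x)))
    event = (t <= censor).astype(int)
    time = np.minimum(t, censor) + 1e-9
    return SurvivalData(time, event, pd.DataFrame({"x": x}))


class TestContingency:
    def test_printed_worked_examples(self):
        _, p = pearson_chi2([[15, 11], [14, 10]])
        assert round(p, 3) == 0.963
        _, p = pearson_chi2([[14, 10], [22, 4]])
        assert round(p, 3) == 0.039

    def test_independence(self):
        stat, p = pearson_chi2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [5, 5]])

    def test_fisher_printed_example(self):
        assert round(fisher_exact([[29, 10], [7, 4]]), 3) == 0.476

    def test_fisher_two_table_margin(self):
        assert fisher_exact([[1, 0], [0, 1]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_fisher_matches_hypergeometric_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 12, 4)
        table = [[a + 1, b], [c, d + 1]]
        r1, r2 = a + 1 + b, c + d + 1
        c1 = a + 1 + c
        n = r1 + r2
        rv = sps.hypergeom(n, r1, c1)
        probs = rv.pmf(np.arange(max(0, c1 - r2), min(r1, c1) + 1))
        p_obs = rv.pmf(a + 1)
        expected = probs[probs <= p_obs * (1 + 1e-9)].sum()
        assert fisher_exact(table) == pytest.approx(expected, rel=1e-9)


class TestTAndRank:
    def test_identical_samples(self):
        t, p = t_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_power_sanity(self, rng):
        x = rng.normal(0, 1, 1000)
        y = rng.normal(1, 1, 1000)
        assert t_test(x, y)[1] < 1e-10
        assert mann_whitney(x, y)[1] < 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_u_statistic_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 10, 7).astype(float)
        y = rng.integers(0, 10, 6).astype(float)
        u_brute = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
        assert mann_whitney(x, y)[0] == pytest.approx(u_brute)


class TestKaplanMeier:
    def test_no_censoring_steps_and_median(self):
        times = np.arange(1.0, 11.0)
        data = SurvivalData(times, np.ones(10, int))
        km = km_estimate(data)
        # S drops by 1/10 at each event; median = first t with S <= 0.5
        assert km.survival[km.times == 5.0][0] == pytest.approx(0.5)
        assert km.median == 5.0

    def test_km_equals_one_minus_ecdf_without_censoring(self, rng):
        t = rng.exponential(10, 300) + 0.01
        data = SurvivalData(t, np.ones(300, int))
        km = km_estimate(data)
        for ti, si in zip(km.times[1:], km.survival[1:]):
            assert si == pytest.approx(1 - np.mean(t <= ti), abs=1e-10)

    def test_median_undefined_when_curve_stays_high(self):
        data = SurvivalData([10.0, 20, 30, 40], [1, 0, 0, 0])
        km = km_estimate(data)
        assert np.isinf(km.median)

    def test_exponential_group_medians_closed_form(self, rng):
        lam = 0.05
        t1 = rng.exponential(1 / lam, 400) + 1e-6
        t2 = rng.exponential(1 / (5 * lam), 400) + 1e-6
        data = SurvivalData(np.r_[t1, t2], np.ones(800, int))
        group = np.r_[np.zeros(400), np.ones(400)]
        km = km_estimate(data, group)
        assert km[0.0].median == pytest.approx(math.log(2) / lam, rel=0.15)
        assert km[1.0].median == pytest.approx(math.log(2) / (5 * lam), rel=0.15)


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.arange(1.0, 21.0)
        data = SurvivalData(np.r_[t, t], np.ones(40, int))
        group = np.r_[np.zeros(20), np.ones(20)]
        chi2, p = logrank_test(data, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lifelines(self, seed):
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(seed)
        data = sim_survival(rng, n=120, hr=2.0)
        g = data.covariates["x"].to_numpy() == 1
        chi2, p = logrank_test(data, g)
        ref = ll(data.time[g], data.time[~g], data.event[g], data.event[~g])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-6)
        assert p == pytest.approx(ref.p_value, rel=1e-6)


class TestCox:
    def test_recovers_generating_hr(self, rng):
        data = sim_survival(rng, n=1000, hr=5.0, censor=200.0)
        fit = cox_fit(data, ["x"])
        assert 4.0 <= fit.hr[0] <= 6.25
        assert fit.ci_low[0] < 5.0 < fit.ci_high[0]

    def test_null_covariate_calibrated(self):
        extreme = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            data = sim_survival(rng, n=150, hr=1.0)
            fit = cox_fit(data, ["x"])
            extreme += abs(fit.coef[0] / fit.se[0]) >= 3
        assert extreme <= 2

    def test_wald_agrees_with_logrank_first_order(self, rng):
        data = sim_survival(rng, n=300, hr=2.0)
        fit = cox_fit(data, ["x"])
        _, p_lr = logrank_test(data, data.covariates["x"].to_numpy() == 1)
        # asymptotically equivalent tests: log p-values agree to ~5%
        assert math.log(fit.p[0]) == pytest.approx(math.log(p_lr), rel=0.10)

    def test_breslow_close_to_efron_with_few_ties(self, rng):
        data = sim_survival(rng, n=300, hr=3.0)
        fe = cox_fit(data, ["x"], ties="efron")
        fb = cox_fit(data, ["x"], ties="breslow")
        assert fb.coef[0] == pytest.approx(fe.coef[0], abs=0.05)

    def test_constant_covariate_rejected(self, rng):
        data = sim_survival(rng, n=50)
        data.covariates["x"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_fit(data, ["x"])


class TestPHTest:
    def test_null_not_rejected_too_often(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = sim_survival(rng, n=200, hr=2.0)
            fit = cox_fit(data, ["x"])
            rejections += ph_test(fit).loc["GLOBAL", "p"] < 0.05
        assert rejections <= 4

    def test_reversing_effect_detected(self):
        """Piecewise-exponential hazard whose covariate effect flips sign at
        t0 violates proportionality and must be flagged."""
        rng = np.random.default_rng(2)
        n, t0, r, beta = 500, 20.0, 0.0347, 1.2
        x = (rng.random(n) < 0.5).astype(float)
        u = rng.random(n)
        rate1 = r * np.exp(beta * x)
        rate2 = r * np.exp(-beta * x)
        t = np.where(
            -np.log(u) < rate1 * t0,
            -np.log(u) / rate1,
            t0 + (-np.log(u) - rate1 * t0) / rate2,
        )
        data = SurvivalData(t + 1e-9, np.ones(n, int), pd.DataFrame({"x": x}))
        fit = cox_fit(data, ["x"])
        res = ph_test(fit)
        assert res.loc["x", "p"] < 0.01
        assert res.loc["GLOBAL", "p"] < 0.01


class TestTdROC:
    def test_perfect_marker(self, rng):
        t = np.sort(rng.exponential(20, 100)) + 0.01
        data = SurvivalData(t, np.ones(100, int))
        marker = -t  # exact risk order
        res = td_roc(marker, data, [np.median(t)], n_boot=10, seed=0)
        assert res["auc"].iloc[0] == pytest.approx(1.0)

    def test_null_marker(self, rng):
        t = rng.exponential(20, 400) + 0.01
        data = SurvivalData(t, np.ones(400, int))
        res = td_roc(rng.normal(size=400), data, [15.0], n_boot=10, seed=0)
        assert res["auc"].iloc[0] == pytest.approx(0.5, abs=0.08)

    def test_uncensored_equals_pair_counting(self, rng):
        n = 150
        t = rng.exponential(20, n) + 0.01
        marker = -t + rng.normal(0, 5, n)
        data = SurvivalData(t, np.ones(n, int))
        horizon = float(np.median(t))
        res = td_roc(marker, data, [horizon], n_boot=0)
        cases = marker[t <= horizon]
        ctrls = marker[t > horizon]
        brute = np.mean(
            [(ci > cj) + 0.5 * (ci == cj) for ci in cases for cj in ctrls]
        )
        assert res["auc"].iloc[0] == pytest.approx(brute, abs=1e-8)

    def test_horizon_validation(self, rng):
        data = SurvivalData(rng.exponential(20, 50) + 0.01, np.ones(50, int))
        with pytest.raises(ValueError):
            td_roc(np.zeros(50), data, [data.time.max() + 1], n_boot=0)


class TestCIndex:
    def test_perfect_and_constant(self, rng):
        t = rng.exponential(10, 50) + 0.01
        data = SurvivalData(t, np.ones(50, int))
        assert c_index(-t, data) == pytest.approx(1.0)
        assert c_index(np.zeros(50), data) == pytest.approx(0.5)

    def test_matches_quadratic_scan(self, rng):
        n = 200
        data = sim_survival(rng, n=n, hr=3.0)
        marker = data.covariates["x"].to_numpy() + rng.normal(0, 0.2, n)
        num = den = 0.0
        for i in range(n):
            for j in range(n):
                if data.event[i] == 1 and data.time[i] < data.time[j]:
                    den += 1
                    if marker[i] > marker[j]:
                        num += 1
                    elif marker[i] == marker[j]:
                        num += 0.5
        assert c_index(marker, data) == pytest.approx(num / den, abs=1e-10)


class TestLRTAndNRI:
    def test_identical_models(self, rng):
        data = sim_survival(rng, n=150, hr=3.0)
        fit = cox_fit(data, ["x"])
        chi2, df, p = lrt_nested(fit, fit)
        assert chi2 == pytest.approx(0.0, abs=1e-9) and df == 0 and p == 1.0

    def test_strong_predictor_improves_fit(self, rng):
        data = sim_survival(rng, n=500, hr=5.0)
        data.covariates["noise"] = rng.normal(size=500)
        full = cox_fit(data, ["x", "noise"])
        reduced = cox_fit(data, ["noise"])
        chi2, df, p = lrt_nested(full, reduced)
        assert df == 1 and p < 1e-4

    def test_nri_identity_and_bound(self):
        old = np.array([0.1, 0.4, 0.9, 0.2])
        out = np.array([1, 1, 0, 0])
        assert nri(old, old, out, [0.3, 0.6])[0] == 0.0
        # perfect reclassification: every event up, every non-event down
        new = np.where(out == 1, 0.99, 0.01)
        worst_old = np.where(out == 1, 0.01, 0.99)
        assert nri(worst_old, new, out, [0.5])[0] == pytest.approx(2.0)

    def test_nri_hand_fixture(self):
        # 3 categories via thresholds [0.2, 0.6]
        old = np.array([0.1, 0.1, 0.4, 0.4, 0.7, 0.7, 0.1, 0.7])
        new = np.array([0.4, 0.1, 0.7, 0.1, 0.7, 0.4, 0.4, 0.7])
        out = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        # events: up, same, up, down -> (2-1)/4 ; nonevents: same, down, up, same -> (1-1)/4
        total, ev, ne = nri(old, new, out, [0.2, 0.6])
        assert ev == pytest.approx(0.25)
        assert ne == pytest.approx(0.0)
        assert total == pytest.approx(0.25)


class TestROCCutoff:
    def test_separated_classes(self):
        res = roc_cutoff([1.0, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res["auc"] == 1.0
        assert 3 < res["cutoff"] <= 10

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_mann_whitney_identity(self, seed):
        rng = np.random.default_rng(seed)
        marker = rng.normal(size=60)
        label = rng.random(60) < 0.4
        marker[label] += 0.8
        u, _ = mann_whitney(marker[label], marker[~label])
        auc_mwu = u / (label.sum() * (~label).sum())
        assert roc_cutoff(marker, label)["auc"] == pytest.approx(auc_mwu, rel=1e-10)

    def test_ci_brackets_auc(self, rng):
        marker = rng.normal(size=100)
        label = rng.random(100) < 0.5
        res = roc_cutoff(marker, label)
        lo, hi = res["auc_ci"]
        assert lo <= res["auc"] <= hi
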