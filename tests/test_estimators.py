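"""MR estimator suite: exact fixtures, oracles, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from triangmr import estimators as est
from triangmr.simulate import MRScenario, simulate_mr_arrays


def _pairs(bx, sx, by, sy, eaf=None):
    d = {"exposure_beta": np.asarray(bx, float),
         "exposure_se": np.asarray(sx, float),
         "outcome_beta": np.asarray(by, float),
         "outcome_se": np.asarray(sy, float)}
    if eaf is not None:
        d["exposure_eaf"] = np.asarray(eaf, float)
        d["outcome_eaf"] = np.asarray(eaf, float)
    return d


def random_pairs(rng, m=12):
    bx = rng.normal(0.1, 0.05, m)
    bx[np.abs(bx) < 0.02] = 0.05
    return _pairs(bx, np.abs(rng.normal(0.01, 0.002, m)),
                  rng.normal(0.03, 0.02, m),
                  np.abs(rng.normal(0.01, 0.003, m)))


class TestRatio:
    @pytest.mark.parametrize("bx, by, sy, exp_r, exp_se", [
        (0.5, 0.1, 0.05, 0.2, 0.1),
        (-0.5, 0.1, 0.05, -0.2, 0.1),
    ])
    def test_arithmetic(self, bx, by, sy, exp_r, exp_se):
        r, se = est.ratio_estimates(_pairs([bx], [0.01], [by], [sy]))
        assert r[0] == pytest.approx(exp_r)
        assert se[0] == pytest.approx(exp_se)

    def test_zero_exposure_beta_excluded(self, rng):
        p = _pairs([0.0, 0.5], [0.01, 0.01], [0.1, 0.1], [0.05, 0.05])
        with pytest.warns(UserWarning, match="exposure beta = 0"):
            r, se = est.ratio_estimates(p)
        assert len(r) == 1

    def test_matches_direct_reevaluation(self, rng):
        p = random_pairs(rng, 10)
        r, se = est.ratio_estimates(p)
        np.testing.assert_allclose(r, p["outcome_beta"] / p["exposure_beta"])
        np.testing.assert_allclose(
            se, p["outcome_se"] / np.abs(p["exposure_beta"]))


class TestIVW:
    def test_exact_proportionality(self, simple_pairs):
        r = est.ivw_estimate(simple_pairs)
        assert r.beta == pytest.approx(0.3, abs=1e-12)
        assert r.heterogeneity_q == pytest.approx(0.0, abs=1e-20)
        # random-effects scaling floored at 1: SE equals the fixed-effect SE
        assert r.se == pytest.approx(r.extras["se_fixed"])

    def test_single_variant_wald_fallback(self):
        r = est.ivw_estimate(_pairs([0.5], [0.01], [0.1], [0.05]))
        assert r.method == "Wald"
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.1)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm
        p = random_pairs(rng)
        r = est.ivw_estimate(p)
        ratio, ratio_se = est.ratio_estimates(p)
        fit = sm.WLS(ratio, np.ones(len(ratio)),
                     weights=1 / ratio_se ** 2).fit()
        assert r.beta == pytest.approx(fit.params[0], rel=1e-10)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.linspace(0.05, 0.2, 6)
        r = est.egger_estimate(_pairs(bx, np.zeros(6), 0.1 + 0.4 * bx,
                                      np.full(6, 0.01)))
        assert r.extras["egger_intercept"] == pytest.approx(0.1, abs=1e-10)
        assert r.beta == pytest.approx(0.4, abs=1e-10)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm
        p = random_pairs(rng, 15)
        r = est.egger_estimate(p)
        flip = np.sign(p["exposure_beta"])
        X = sm.add_constant(p["exposure_beta"] * flip)
        fit = sm.WLS(p["outcome_beta"] * flip, X,
                     weights=1 / p["outcome_se"] ** 2).fit()
        assert r.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert r.extras["egger_intercept"] == pytest.approx(fit.params[0],
                                                            rel=1e-10)

    def test_too_few_variants(self):
        r = est.egger_estimate(_pairs([0.1, 0.2], [0, 0], [0.05, 0.1],
                                      [0.01, 0.01]))
        assert not r.estimable and ">= 3" in r.reason


def weighted_median_oracle(ratios, weights):
    """Brute-force weighted percentile with linear interpolation."""
    order = np.argsort(ratios)
    b = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    cum = (np.cumsum(w) - w / 2) / w.sum()
    if 0.5 <= cum[0]:
        return b[0]
    for j in range(1, len(b)):
        if cum[j] >= 0.5:
            return b[j - 1] + (b[j] - b[j - 1]) * \
                (0.5 - cum[j - 1]) / (cum[j] - cum[j - 1])
    return b[-1]


class TestWeightedMedian:
    def test_equal_weights_median(self):
        bx = np.ones(3)
        by = np.array([0.1, 0.2, 0.3])
        r = est.weighted_median_estimate(_pairs(bx, np.zeros(3), by,
                                                np.ones(3)), seed=0)
        assert r.beta == pytest.approx(0.2)

    def test_unequal_weights_match_oracle(self, rng):
        by = np.array([0.05, 0.11, 0.2, 0.33])
        sy = np.array([0.01, 0.03, 0.02, 0.05])
        p = _pairs(np.ones(4), np.zeros(4), by, sy)
        r = est.weighted_median_estimate(p, seed=0)
        assert r.beta == pytest.approx(
            weighted_median_oracle(by, 1 / sy ** 2), rel=1e-12)

    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=12),
           st.integers(0, 10_000))
    def test_oracle_equivalence_property(self, ratios, seed):
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.1, 5.0, len(ratios))
        from triangmr.estimators import weighted_median
        assert weighted_median(ratios, w) == pytest.approx(
            weighted_median_oracle(ratios, w), rel=1e-9, abs=1e-12)

    def test_penalty_inactive_on_homogeneous_data(self, simple_pairs):
        a = est.weighted_median_estimate(simple_pairs, penalized=False,
                                         seed=1)
        b = est.weighted_median_estimate(simple_pairs, penalized=True, seed=1)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)

    def test_breakdown_robustness_vs_ivw(self):
        # 40% of instruments grossly pleiotropic: WM stays near the truth
        rng = np.random.default_rng(3)
        scen = MRScenario(m_instruments=20, beta_causal=0.2)
        wm_err, ivw_err = [], []
        for i in range(50):
            d = simulate_mr_arrays(scen, rng=rng)
            by = d["by"].copy()
            by[:8] += 0.1  # invalid minority, one-directional
            p = _pairs(d["bx"], d["sx"], by, d["sy"])
            wm_err.append(est.weighted_median_estimate(p, seed=i).beta - 0.2)
            ivw_err.append(est.ivw_estimate(p).beta - 0.2)
        assert abs(np.mean(wm_err)) < abs(np.mean(ivw_err))


class TestPresso:
    def test_clean_data_no_outliers_equals_ivw(self, rng):
        scen = MRScenario(m_instruments=20, beta_causal=0.2, seed=8)
        d = simulate_mr_arrays(scen)
        p = _pairs(d["bx"], d["sx"], d["by"], d["sy"])
        r = est.presso(p, n_sim=500, seed=1)
        assert r.extras["global_p"] > 0.05
        assert r.extras["outliers"] == []
        assert r.beta == pytest.approx(est.ivw_estimate(p).beta)

    def test_outlier_removed_estimate_is_headline(self):
        # one grossly pleiotropic variant: headline mirrors the convention
        # of reporting outlier-corrected results when the global test fires
        scen = MRScenario(m_instruments=30, beta_causal=0.1, seed=4)
        d = simulate_mr_arrays(scen)
        by = d["by"].copy()
        by[0] += 12 * d["sy"][0]
        p = _pairs(d["bx"], d["sx"], by, d["sy"])
        r = est.presso(p, n_sim=1000, seed=2)
        assert r.extras["global_p"] < 0.05
        assert 0 in r.extras["outliers"]
        keep = np.setdiff1d(np.arange(30), r.extras["outliers"])
        corrected = est.ivw_estimate(
            _pairs(d["bx"][keep], d["sx"][keep], by[keep], d["sy"][keep]))
        assert r.beta == pytest.approx(corrected.beta)
        assert r.extras["raw_beta"] != pytest.approx(r.beta)

    def test_insufficient_resolution_warns(self):
        d = simulate_mr_arrays(MRScenario(m_instruments=20, seed=0))
        with pytest.warns(UserWarning, match="cannot resolve"):
            est.presso(_pairs(d["bx"], d["sx"], d["by"], d["sy"]),
                       n_sim=100, seed=0)


class TestRaps:
    def test_noiseless_proportional_recovers_slope(self):
        bx = np.linspace(0.05, 0.2, 8)
        r = est.raps_estimate(_pairs(bx, np.zeros(8), 0.25 * bx,
                                     np.full(8, 0.01)))
        assert r.beta == pytest.approx(0.25, abs=1e-8)

    def test_zero_exposure_noise_limit_equals_fixed_ivw(self, rng):
        p = random_pairs(rng, 15)
        p["exposure_se"] = np.zeros(15)
        r = est.raps_estimate(p)
        w = 1 / p["outcome_se"] ** 2
        ivw_fixed = np.sum(w * p["exposure_beta"] * p["outcome_beta"]) / \
            np.sum(w * p["exposure_beta"] ** 2)
        assert r.beta == pytest.approx(ivw_fixed, abs=1e-8)

    def test_overdispersion_detects_extra_variance(self):
        rng = np.random.default_rng(10)
        scen = MRScenario(m_instruments=50, beta_causal=0.1,
                          pleiotropy_sd=0.02)
        taus = []
        for _ in range(20):
            d = simulate_mr_arrays(scen, rng=rng)
            r = est.raps_estimate(
                _pairs(d["bx"], d["sx"], d["by"], d["sy"]),
                overdispersion=True)
            taus.append(r.extras["tau2"])
        assert np.mean(taus) == pytest.approx(0.02 ** 2, rel=0.5)

    def test_huber_loss_close_to_simple_on_clean_data(self, rng):
        p = random_pairs(rng, 20)
        a = est.raps_estimate(p, loss="simple")
        b = est.raps_estimate(p, loss="huber")
        assert b.beta == pytest.approx(a.beta, abs=3 * a.se)


class TestSteiger:
    def test_direction_forced_by_r2_inequality(self):
        p = _pairs([0.3], [0.01], [0.03], [0.01], eaf=[0.3])
        r = est.steiger_test(p, 50_000, 50_000)
        assert r.direction_correct and r.pvalue < 0.05

    def test_equal_r2_indeterminate(self):
        p = _pairs([0.1], [0.01], [0.1], [0.01], eaf=[0.3])
        r = est.steiger_test(p, 50_000, 50_000)
        assert r.pvalue == 1.0 and r.z_statistic == 0.0 and r.indeterminate

    def test_unstandardized_betas_rejected(self):
        p = _pairs([5.0, 5.0], [0.1, 0.1], [0.1, 0.1], [0.1, 0.1],
                   eaf=[0.5, 0.5])
        with pytest.raises(ValueError, match="standardized"):
            est.steiger_test(p, 50_000, 50_000)


class TestMVMR:
    def test_single_exposure_reduces_to_ivw_outcome_weights(self, rng):
        p = random_pairs(rng, 10)
        fit = est.mvmr_fit(p["exposure_beta"], p["outcome_beta"],
                           p["outcome_se"])[0]
        w = 1 / p["outcome_se"] ** 2
        slope = np.sum(w * p["exposure_beta"] * p["outcome_beta"]) / \
            np.sum(w * p["exposure_beta"] ** 2)
        assert fit.beta == pytest.approx(slope, rel=1e-12)

    def test_null_second_exposure_noiseless(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0.1, 0.03, 12)
        x2 = np.zeros(12)
        X = np.column_stack([x1, x2 + rng.normal(0, 1e-6, 12)])
        by = 0.4 * x1
        fits = est.mvmr_fit(X, by, np.full(12, 0.01))
        assert fits[0].beta == pytest.approx(0.4, abs=1e-3)
        assert fits[1].beta == pytest.approx(0.0, abs=1e-2)

    def test_matches_statsmodels_wls(self, rng):
        import statsmodels.api as sm
        X = rng.normal(0.1, 0.05, (20, 2))
        by = X @ [0.2, -0.1] + rng.normal(0, 0.01, 20)
        sy = np.abs(rng.normal(0.01, 0.002, 20))
        fits = est.mvmr_fit(X, by, sy)
        oracle = sm.WLS(by, X, weights=1 / sy ** 2).fit()
        np.testing.assert_allclose([f.beta for f in fits], oracle.params,
                                   rtol=1e-10)

    def test_collinear_exposures_named(self, rng):
        x = rng.normal(0.1, 0.05, 15)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear"):
            est.mvmr_fit(X, x, np.full(15, 0.01),
                         exposure_names=["bmi", "whr"])


class TestEstimatorInvariants:
    @pytest.mark.parametrize("fn", [
        est.ivw_estimate, est.egger_estimate,
        lambda p: est.weighted_median_estimate(p, seed=0),
        lambda p: est.raps_estimate(p),
    ])
    def test_sign_flip_equivariance(self, rng, fn):
        p = random_pairs(rng, 12)
        flipped = dict(p)
        flipped["exposure_beta"] = -p["exposure_beta"]
        a, b = fn(p), fn(flipped)
        assert b.beta == pytest.approx(-a.beta, rel=1e-6, abs=1e-9)

    def test_ci_is_exponentiated_normal_interval(self, rng):
        p = random_pairs(rng, 10)
        for r in (est.ivw_estimate(p), est.egger_estimate(p),
                  est.weighted_median_estimate(p, seed=0),
                  est.raps_estimate(p)):
            assert r.ci_low == pytest.approx(np.exp(r.beta - 1.96 * r.se),
                                             rel=1e-3)
            assert r.ci_high == pytest.approx(np.exp(r.beta + 1.96 * r.se),
                                              rel=1e-3)
            assert r.ci_low <= r.or_value <= r.ci_high

    def test_estimators_agree_without_pleiotropy(self):
        # strong instruments, no pleiotropy: all methods estimate the same
        # causal slope within Monte-Carlo error
        rng = np.random.default_rng(17)
        scen = MRScenario(m_instruments=50, beta_causal=0.15)
        means = {k: [] for k in ("ivw", "wm", "pwm", "egger", "raps")}
        for i in range(100):
            d = simulate_mr_arrays(scen, rng=rng)
            p = _pairs(d["bx"], d["sx"], d["by"], d["sy"])
            means["ivw"].append(est.ivw_estimate(p).beta)
            means["wm"].append(
                est.weighted_median_estimate(p, seed=i, n_boot=100).beta)
            means["pwm"].append(est.weighted_median_estimate(
                p, penalized=True, seed=i, n_boot=100).beta)
            means["egger"].append(est.egger_estimate(p).beta)
            means["raps"].append(est.raps_estimate(p).beta)
        for k, v in means.items():
            mc_se = np.std(v) / np.sqrt(len(v))
            assert abs(np.mean(v) - 0.15) < 3 * max(mc_se, 1e-3), k
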