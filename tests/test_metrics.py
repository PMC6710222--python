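"""Selection-metric checks against brute-force oracles and closed forms."""

import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import chi2

import lbaselect as lb
from lbaselect.metrics import RopeBounds, chi2_select, rope_select
from lbaselect.sampler import TemperatureLadder
from lbaselect.toys import BetaBinomialToy, NormalNormalToy


class TestInformationCriteria:
    def test_aic_arithmetic(self):
        assert lb.aic(-100.0, 7).value == pytest.approx(214.0)
        assert lb.aic(-50.0, 0).value == pytest.approx(100.0)

    def test_bic_arithmetic(self):
        assert lb.bic(-100.0, 7, 1).value == pytest.approx(200.0)
        assert lb.bic(-100.0, 7, 600).value == pytest.approx(200 + 7 * np.log(600))

    def test_bic_minus_aic_identity(self):
        # BIC - AIC = k (log n - 2) for any fit
        L, k, n = -321.4, 8, 600
        assert lb.bic(L, k, n).value - lb.aic(L, k).value == pytest.approx(
            k * (np.log(n) - 2)
        )

    def test_dic_hand_cases(self):
        r = lb.dic(np.array([-10.0, -12.0]))
        assert r.extra["d_bar"] == pytest.approx(-11.0)
        assert r.extra["p_d"] == pytest.approx(1.0)
        assert r.value == pytest.approx(24.0)
        const = lb.dic(np.full(50, -3.3))
        assert const.extra["p_d"] == pytest.approx(0.0)
        assert const.value == pytest.approx(6.6)

    def test_dic_brute_force(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-200, 5, size=5000)
        r = lb.dic(ll)
        d_bar = sum(ll) / len(ll)
        p_d = max(ll) - d_bar
        assert r.value == pytest.approx(-2 * (d_bar - p_d), rel=1e-12)

    def test_waic_single_draw(self):
        mat = np.array([[-1.0, -2.0, -3.0]])
        r = lb.waic(mat)
        assert r.extra["p_waic"] == 0.0
        assert r.value == pytest.approx(-2 * mat.sum())

    def test_waic_two_draws_one_trial(self):
        mat = np.array([[-1.0], [-3.0]])
        r = lb.waic(mat)
        lpd = np.log((np.exp(-1) + np.exp(-3)) / 2)
        penalty = np.var([-1.0, -3.0], ddof=1)  # sample variance
        assert r.extra["lpd"] == pytest.approx(lpd)
        assert r.extra["p_waic"] == pytest.approx(penalty)
        assert r.value == pytest.approx(-2 * (lpd - penalty))

    def test_waic_brute_force(self):
        rng = np.random.default_rng(1)
        mat = rng.normal(-2, 0.5, size=(100, 50))
        r = lb.waic(mat)
        lpd = sum(
            logsumexp(mat[:, i]) - np.log(100) for i in range(50)
        )
        pen = sum(np.var(mat[:, i], ddof=1) for i in range(50))
        assert r.value == pytest.approx(-2 * (lpd - pen), rel=1e-12)

    def test_dic_p_reduces_to_dic_under_flat_prior(self):
        rng = np.random.default_rng(2)
        ll = rng.normal(-100, 3, size=1000)
        assert lb.dic_p(ll + 0.0).value == pytest.approx(lb.dic(ll).value)

    def test_metrics_invariant_to_draw_order(self):
        rng = np.random.default_rng(3)
        ll = rng.normal(-100, 3, size=999)
        mat = rng.normal(-2, 0.5, size=(99, 7))
        perm = rng.permutation(999)
        pmat = mat[rng.permutation(99)]
        assert lb.dic(ll[perm]).value == pytest.approx(lb.dic(ll).value, rel=1e-12)
        assert lb.waic(pmat).value == pytest.approx(lb.waic(mat).value, rel=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            lb.dic(np.array([]))
        with pytest.raises(ValueError):
            lb.waic(np.empty((0, 5)))


class TestChiSquareTree:
    def test_equal_deviances_select_null(self):
        d = {v: 100.0 for v in ("null", "drift", "threshold", "complex")}
        assert chi2_select(d).variant == "null"

    def test_single_effect_selected(self):
        d = {"null": 100.0, "drift": 90.0, "threshold": 95.0, "complex": 89.0}
        res = chi2_select(d, alpha=0.05)
        # null vs drift: 10 on 1 df significant; drift vs complex: 1 on 1 df not
        assert chi2.sf(10, 1) < 0.05 < chi2.sf(1, 1)
        assert res.variant == "drift"

    def test_null_retained_when_gains_small(self):
        d = {"null": 100.0, "drift": 99.5, "threshold": 99.6, "complex": 99.0}
        res = chi2_select(d, alpha=0.05)
        # 0.5 on 1 df ns; null vs complex: 1.0 on 2 df ns
        assert chi2.sf(0.5, 1) > 0.05 and chi2.sf(1.0, 2) > 0.05
        assert res.variant == "null"

    def test_complex_selected_via_two_df_branch(self):
        d = {"null": 100.0, "drift": 99.9, "threshold": 99.8, "complex": 80.0}
        assert chi2_select(d).variant == "complex"

    def test_missing_variant_errors(self):
        with pytest.raises(ValueError):
            chi2_select({"null": 1.0, "drift": 1.0})


class TestRope:
    def test_no_difference_means_absent(self):
        res = rope_select(np.zeros(100), np.zeros(100))
        assert res.variant == "null"
        assert res.extra["prop_outside"] == {"v_c": 0.0, "b": 0.0}

    def test_large_drift_difference_detected(self):
        res = rope_select(np.ones(100), np.zeros(100))
        assert res.variant == "drift"

    def test_majority_inside_means_absent(self):
        draws = np.concatenate([np.zeros(60), np.ones(40)])
        res = rope_select(draws, np.full(100, 0.5))
        assert res.extra["prop_outside"]["v_c"] == pytest.approx(0.4)
        assert res.variant == "threshold"  # b diff 0.5 outside [-0.11, 0.11]

    def test_tie_counts_as_absent(self):
        draws = np.concatenate([np.zeros(50), np.ones(50)])
        assert rope_select(draws, np.zeros(100)).variant == "null"

    def test_bounds_must_straddle_zero(self):
        with pytest.raises(ValueError):
            RopeBounds(v_c=(0.1, 0.3))


class TestMarginalLikelihood:
    def test_ti_flat_integrand(self):
        lad = TemperatureLadder(np.linspace(0, 1, 11), np.full(11, -7.5))
        assert lb.ti_logml(lad).value == pytest.approx(-7.5)

    def test_ti_single_trapezoid(self):
        lad = TemperatureLadder(np.array([0.0, 1.0]), np.array([-10.0, -2.0]))
        assert lb.ti_logml(lad).value == pytest.approx(-6.0)

    def test_ti_rejects_bad_ladders(self):
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([0.0, 0.5, 0.4, 1.0]))
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([0.2, 1.0]))

    def test_bridge_normal_normal_conjugate(self):
        rng = np.random.default_rng(11)
        toy = NormalNormalToy(rng.normal(1.0, 1.0, 30), sigma=1.0, mu0=0.0, tau0=1.5)
        s = lb.demcmc_sample(toy, n_chains=10, burn=500, keep=1000, seed=12)
        r = lb.bridge_logml(s, toy.log_unnormalized_posterior, seed=13)
        assert r.extra["converged"]
        assert r.value == pytest.approx(toy.log_ml(), abs=0.05)

    def test_bridge_beta_binomial_conjugate(self):
        toy = BetaBinomialToy(y=17, n=40, a=2.0, b=2.0)
        s = lb.demcmc_sample(toy, n_chains=10, burn=500, keep=1000, seed=14)
        r = lb.bridge_logml(s, toy.log_unnormalized_posterior, seed=15)
        assert r.value == pytest.approx(toy.log_ml(), abs=0.05)

    def test_ti_normal_normal_conjugate(self):
        rng = np.random.default_rng(16)
        toy = NormalNormalToy(rng.normal(1.0, 1.0, 30), sigma=1.0, mu0=0.0, tau0=1.5)
        lad = lb.power_posterior_run(toy, n_temperatures=40, burn=300, keep=800, seed=17)
        assert lb.ti_logml(lad).value == pytest.approx(toy.log_ml(), abs=0.1)

    def test_bridge_and_ti_agree_on_small_lba_fit(self):
        data = lb.simulate_trials([lb.BASELINE, lb.BASELINE], 25, seed=18)
        model = lb.LBAModel(data, "null")
        s = lb.demcmc_sample(model, burn=1000, keep=2000, seed=19, store_per_trial=False)
        bs = lb.bridge_logml(s, model.log_unnormalized_posterior, seed=20).value
        lad = lb.power_posterior_run(
            model, n_temperatures=64, burn=1500, keep=8000, seed=21
        )
        ti = lb.ti_logml(lad).value
        assert bs == pytest.approx(ti, abs=0.2)
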