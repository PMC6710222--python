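"""Density, likelihood, and simulator checks for the LBA core."""

import numpy as np
import pytest
from scipy.integrate import quad

import lbaselect as lb
from lbaselect import _kernels
from lbaselect.lba import DENSITY_FLOOR


def random_param_sets(n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        A = rng.uniform(0.2, 2.0)
        out.append(
            dict(
                b=A + rng.uniform(0.1, 2.0),
                A=A,
                v=rng.uniform(0.5, 4.0),
                sv=rng.uniform(0.5, 2.0),
            )
        )
    return out


class TestNodeDensity:
    def test_zero_before_accumulation_starts(self):
        assert lb.node_density(-0.1, 2, 1, 3, 1) == 0.0
        assert lb.node_density(0.0, 2, 1, 3, 1) == 0.0

    @pytest.mark.parametrize("ps", random_param_sets(20), ids=lambda p: f"v{p['v']:.1f}b{p['b']:.1f}")
    def test_integrates_to_one(self, ps):
        # positive-truncated drift: the accumulator finishes almost surely
        total, _ = quad(lambda t: lb.node_density(t, **ps), 0, np.inf, limit=300)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_matches_monte_carlo_histogram(self):
        rng = np.random.default_rng(5)
        n = 10**6
        b, A, v, sv = 2.0, 1.0, 3.0, 1.0
        from scipy.stats import truncnorm

        drift = truncnorm.rvs(-v / sv, np.inf, loc=v, scale=sv, size=n, random_state=rng)
        start = rng.uniform(0, A, n)
        t = (b - start) / drift
        edges = np.linspace(0.05, 3.0, 60)
        counts, _ = np.histogram(t, bins=edges)
        F = lb.node_cdf(edges, b, A, v, sv)
        expected_mass = np.diff(F)
        observed_mass = counts / n
        # binomial MC error per bin, 4 SEs plus a tiny absolute slack
        se = np.sqrt(expected_mass * (1 - expected_mass) / n)
        assert np.all(np.abs(observed_mass - expected_mass) < 4 * se + 1e-5)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            lb.node_density(np.nan, 2, 1, 3, 1)
        with pytest.raises(ValueError):
            lb.node_density(0.5, 1, 2, 3, 1)  # b < A
        with pytest.raises(ValueError):
            lb.node_density(0.5, 2, 1, 3, 0.0)


class TestNodeCdf:
    def test_limits(self):
        assert lb.node_cdf(0.0, 2, 1, 3, 1) == 0.0
        assert lb.node_cdf(1e6, 2, 1, 3, 1) == pytest.approx(1.0, abs=1e-6)

    def test_nondecreasing(self):
        t = np.linspace(0.01, 10, 500)
        F = lb.node_cdf(t, 2, 1, 2.5, 1.2)
        assert np.all(np.diff(F) >= -1e-12)

    @pytest.mark.parametrize("ps", random_param_sets(5, seed=2))
    def test_derivative_matches_density(self, ps):
        h = 1e-6
        for t in (0.3, 0.6, 1.0, 2.0):
            num = (lb.node_cdf(t + h, **ps) - lb.node_cdf(t - h, **ps)) / (2 * h)
            assert num == pytest.approx(lb.node_density(t, **ps), rel=1e-4, abs=1e-8)


class TestDefectiveDensity:
    @pytest.mark.parametrize("seed", range(8))
    def test_responses_integrate_to_one(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.uniform(0.2, 1.5)
        p = lb.LBAParams(
            v_c=rng.uniform(1, 4), v_e=rng.uniform(0.5, 3), A=A,
            b=A + rng.uniform(0.2, 1.5), t0=rng.uniform(0.1, 0.5),
            sv_e=rng.uniform(0.5, 1.5),
        )
        total = 0.0
        for resp in ("correct", "error"):
            val, _ = quad(
                lambda rt: np.exp(lb.defective_log_density(rt, resp, p)),
                p.t0, np.inf, limit=300,
            )
            total += val
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_symmetric_accumulators_split_evenly(self):
        p = lb.LBAParams(v_c=2.5, v_e=2.5, A=1, b=2, t0=0.2, sv_e=1.0)
        pc, _ = quad(
            lambda rt: np.exp(lb.defective_log_density(rt, "correct", p)),
            p.t0, np.inf, limit=300,
        )
        assert pc == pytest.approx(0.5, abs=1e-4)

    def test_floor_below_nondecision_time(self):
        p = lb.LBAParams(v_c=3, v_e=2, A=1, b=2, t0=0.3)
        assert lb.defective_log_density(0.29, "correct", p) == pytest.approx(
            np.log(DENSITY_FLOOR)
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(TypeError):
            lb.defective_log_density(0.5, "correct", (3, 2, 1, 2, 0.3))


class TestLogLikelihood:
    def test_empty_dataset_is_zero(self):
        spec = lb.build_model("null")
        theta = np.array([3, 2, 1, 1, 1, 0.3])
        assert lb.log_likelihood(lb.ChoiceRTDataset.empty(), spec, theta) == 0.0

    def test_equals_per_trial_loop(self, small_dataset):
        spec = lb.build_model("drift")
        theta = np.array([2.8, 3.4, 2.1, 1.1, 0.9, 1.2, 0.25])
        p1, p2 = lb.theta_to_condition_params(theta, spec)
        expected = sum(
            lb.defective_log_density(rt, "correct" if c else "error", (p1, p2)[cond - 1])
            for rt, c, cond in zip(
                small_dataset.rt, small_dataset.correct, small_dataset.condition
            )
        )
        got = lb.log_likelihood(small_dataset, spec, theta)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_support_violation_is_minus_inf(self, small_dataset):
        spec = lb.build_model("null")
        theta = np.array([3, 2, 1, 1, -0.1, 0.3])  # B = b - A < 0
        assert lb.log_likelihood(small_dataset, spec, theta) == -np.inf

    def test_invariant_to_trial_order(self, small_dataset):
        spec = lb.build_model("null")
        theta = np.array([3, 2, 1, 1, 1, 0.25])
        rng = np.random.default_rng(3)
        perm = rng.permutation(small_dataset.n_trials)
        shuffled = lb.ChoiceRTDataset(
            small_dataset.condition[perm],
            small_dataset.correct[perm],
            small_dataset.rt[perm],
        )
        assert lb.log_likelihood(shuffled, spec, theta) == pytest.approx(
            lb.log_likelihood(small_dataset, spec, theta), rel=1e-12
        )

    def test_kernel_agrees_with_reference_path(self, small_dataset):
        """The numba fast path and the plain scipy/numpy path are the same math."""
        spec = lb.build_model("complex")
        rng = np.random.default_rng(9)
        theta = spec.sample_prior(rng, 1)[0]
        p1, p2 = lb.theta_to_condition_params(theta, spec)
        ref = sum(
            lb.defective_log_density(rt, bool(c), (p1, p2)[cond - 1])
            for rt, c, cond in zip(
                small_dataset.rt, small_dataset.correct, small_dataset.condition
            )
        )
        assert lb.log_likelihood(small_dataset, spec, theta) == pytest.approx(ref, rel=1e-9)


class TestSimulator:
    def test_empty(self):
        d = lb.simulate_trials([lb.BASELINE, lb.BASELINE], 0, seed=0)
        assert d.n_trials == 0

    def test_reproducible(self):
        a = lb.simulate_trials([lb.BASELINE], 200, seed=42)
        b = lb.simulate_trials([lb.BASELINE], 200, seed=42)
        assert np.array_equal(a.rt, b.rt) and np.array_equal(a.correct, b.correct)

    def test_all_rts_exceed_nondecision_time(self):
        d = lb.simulate_trials([lb.BASELINE], 10**5, seed=1)
        assert d.rt.min() > lb.BASELINE.t0

    def test_accuracy_matches_quadrature(self):
        p = lb.BASELINE
        n = 4 * 10**5
        d = lb.simulate_trials([p], n, seed=2)
        p_correct, _ = quad(
            lambda rt: np.exp(lb.defective_log_density(rt, "correct", p)),
            p.t0, np.inf, limit=300,
        )
        se = np.sqrt(p_correct * (1 - p_correct) / n)
        assert abs(d.correct.mean() - p_correct) < 3 * se

    def test_rt_quantiles_match_numeric_cdf(self):
        """Per-response RT quantiles of simulated trials match the defective CDF."""
        p = lb.BASELINE
        n = 2 * 10**5
        d = lb.simulate_trials([p], n, seed=4)
        rts = d.rt[d.correct]
        p_correct = d.correct.mean()
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            target = np.quantile(rts, q)
            # numeric CDF of correct RTs, conditional on a correct response
            val, _ = quad(
                lambda rt: np.exp(lb.defective_log_density(rt, "correct", p)),
                p.t0, target, limit=300,
            )
            assert val / p_correct == pytest.approx(q, abs=0.01)

    def test_invalid_params_error(self):
        with pytest.raises(ValueError):
            lb.LBAParams(v_c=3, v_e=2, A=2, b=1, t0=0.3)  # b < A
        with pytest.raises(ValueError):
            lb.simulate_trials([lb.BASELINE], -1, seed=0)


class TestDatasetContainer:
    def test_csv_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "d.csv"
        small_dataset.to_csv(path)
        back = lb.ChoiceRTDataset.from_csv(path)
        assert np.array_equal(back.condition, small_dataset.condition)
        assert np.array_equal(back.correct, small_dataset.correct)
        np.testing.assert_allclose(back.rt, small_dataset.rt)

    def test_rejects_noncontiguous_conditions(self):
        with pytest.raises(ValueError):
            lb.ChoiceRTDataset(np.array([1, 3]), np.array([True, False]), np.array([0.5, 0.6]))
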