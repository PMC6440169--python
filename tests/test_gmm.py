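"""Mixture fitting, threshold analytics and sequential adaptation."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

import emgonset as eo
from emgonset.gmm import (
    AdaptiveState,
    DegenerateFitError,
    GmmParams,
    _threshold_flagged,
    classify_stream,
    classify_streams,
    em_fit,
    load_models,
    optimal_threshold,
    responsibilities,
    save_models,
    sequential_update,
)


def _draw_mixture(rng, n, w=(0.6, 0.4), mu=(1.0, 5.0), sd=(0.5, 1.0)):
    comp = rng.random(n) < w[1]
    x = np.where(comp, rng.normal(mu[1], sd[1], n), rng.normal(mu[0], sd[0], n))
    return x


class TestEmFit:
    def test_recovery_known_mixture(self):
        rng = np.random.default_rng(42)
        x = _draw_mixture(rng, 10_000)
        fit = em_fit(x, tol=1e-6, max_iter=500)
        p = fit.params
        assert fit.converged and fit.n_iter < 500
        assert p.mu_rest == pytest.approx(1.0, rel=0.02)
        assert p.mu_mov == pytest.approx(5.0, rel=0.02)
        assert p.w_rest == pytest.approx(0.6, abs=0.03)
        assert p.w_mov == pytest.approx(0.4, abs=0.03)

    def test_two_point_mass(self):
        x = np.array([0.0, 10.0] * 200)
        fit = em_fit(x)
        assert fit.params.mu_rest == pytest.approx(0.0, abs=1e-6)
        assert fit.params.mu_mov == pytest.approx(10.0, abs=1e-6)
        assert fit.params.w_rest == pytest.approx(0.5, abs=1e-6)

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateFitError):
            em_fit(np.full(200, 3.0))

    def test_sample_floor(self):
        with pytest.raises(ValueError, match="50"):
            em_fit(np.random.default_rng(0).normal(size=10))

    def test_loglik_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.mixture")
        rng = np.random.default_rng(7)
        x = _draw_mixture(rng, 5000)
        fit = em_fit(x, tol=1e-10, max_iter=2000)
        gm = sklearn.GaussianMixture(
            n_components=2, tol=1e-10, max_iter=2000, n_init=3,
            reg_covar=1e-12, random_state=0,
        ).fit(x[:, None])
        mean_ll_ref = gm.score(x[:, None])
        assert fit.log_likelihood / x.size == pytest.approx(mean_ll_ref, abs=1e-6)


class TestOptimalThreshold:
    def test_symmetric_midpoint(self):
        p = GmmParams(0.5, 0.5, 0.0, 1.0, 1.0, 1.0)
        assert optimal_threshold(p) == pytest.approx(0.5, abs=1e-15)

    def test_unequal_weights_closed_form(self):
        p = GmmParams(0.7, 0.3, 0.0, 1.0, 1.0, 1.0)
        assert optimal_threshold(p) == pytest.approx(0.5 + np.log(7 / 3), abs=1e-10)

    @pytest.mark.parametrize(
        "w,mu,var",
        [
            ((0.5, 0.5), (0.0, 4.0), (1.0, 4.0)),
            ((0.3, 0.7), (-1.0, 2.0), (0.25, 2.0)),
            ((0.8, 0.2), (0.0, 3.0), (2.0, 0.5)),
        ],
    )
    def test_matches_bisection_oracle(self, w, mu, var):
        p = GmmParams(w[0], w[1], mu[0], mu[1], var[0], var[1])

        def diff(x):
            return w[0] * norm.pdf(x, mu[0], np.sqrt(var[0])) - w[1] * norm.pdf(
                x, mu[1], np.sqrt(var[1])
            )

        oracle = brentq(diff, mu[0], mu[1], xtol=1e-14)
        assert optimal_threshold(p) == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_equal_means(self):
        p = GmmParams(0.5, 0.5, 1.0, 1.0, 1.0, 2.0)
        theta, flag = _threshold_flagged(p)
        assert theta == pytest.approx(1.0) and flag

    def test_threshold_between_means_generic(self, rng):
        for _ in range(200):
            mu_r = rng.normal()
            mu_m = mu_r + rng.uniform(0.5, 5)
            p = GmmParams(
                0.5, 0.5, mu_r, mu_m, rng.uniform(0.1, 2), rng.uniform(0.1, 2)
            )
            theta, flag = _threshold_flagged(p)
            if not flag:
                assert mu_r <= theta <= mu_m


class TestResponsibilities:
    def test_midpoint_symmetric(self):
        p = GmmParams(0.5, 0.5, 0.0, 2.0, 1.0, 1.0)
        pr, pm = responsibilities(1.0, p)
        assert pr == pytest.approx(0.5) and pm == pytest.approx(0.5)

    def test_at_rest_mean_well_separated(self):
        p = GmmParams(0.5, 0.5, 0.0, 10.0, 1.0, 1.0)
        pr, _ = responsibilities(0.0, p)
        assert pr > 0.999

    def test_sum_to_one(self, rng):
        p = GmmParams(0.3, 0.7, -1.0, 4.0, 0.5, 2.0)
        for x in rng.normal(scale=20, size=1000):
            pr, pm = responsibilities(float(x), p)
            assert pr + pm == pytest.approx(1.0, abs=1e-12)

    def test_far_tail_underflow_assigns_nearer(self):
        p = GmmParams(0.5, 0.5, 0.0, 1.0, 1e-4, 1e-4)
        pr, pm = responsibilities(1e6, p)
        assert pm == 1.0 and pr == 0.0


class TestSequentialUpdate:
    def _state(self, L=1000):
        p = GmmParams(0.6, 0.4, 1.0, 5.0, 0.25, 1.0)
        return AdaptiveState.from_memory_length(p, L)

    def test_alpha_one_is_noop(self):
        s = AdaptiveState.from_memory_length(
            GmmParams(0.6, 0.4, 1.0, 5.0, 0.25, 1.0), np.inf
        )
        s2 = sequential_update(s, 3.3)
        assert s2.params == s.params and s2.theta == s.theta

    def test_weight_sum_exact(self, rng):
        s = self._state(L=50)
        for x in rng.normal(3.0, 2.0, size=2000):
            s = sequential_update(s, float(x))
            assert s.params.w_rest + s.params.w_mov == 1.0

    def test_stationary_convergence(self):
        rng = np.random.default_rng(5)
        x = _draw_mixture(rng, 100_000)
        init = GmmParams(0.5, 0.5, 0.5, 5.5, 0.5, 1.5)
        res = classify_stream(x, init, L=1000)
        p = res.final_states[0].params
        assert p.mu_rest == pytest.approx(1.0, rel=0.05)
        assert p.mu_mov == pytest.approx(5.0, rel=0.05)

    def test_exponential_forgetting(self):
        """A perturbation's effect on the weights decays as alpha^t."""
        L = 100
        base = self._state(L=L)
        alpha = base.alpha
        s_a = s_b = base
        # identical tails; stream b saw one extra movement-side sample first
        s_b = sequential_update(s_b, 5.0)
        s_a = sequential_update(s_a, 1.0)
        s_b = sequential_update(s_b, 1.0)
        diffs = []
        for x in [1.0] * 30:  # rest-saturated samples keep responsibilities fixed
            d = abs(s_a.params.w_mov - s_b.params.w_mov)
            diffs.append(d)
            s_a = sequential_update(s_a, x)
            s_b = sequential_update(s_b, x)
        ratios = np.array(diffs[1:]) / np.array(diffs[:-1])
        np.testing.assert_allclose(ratios, alpha, rtol=0.02)

    def test_variance_floor_flagged(self):
        p = GmmParams(0.5, 0.5, 0.0, 5.0, 1e-29, 1.0)
        s = AdaptiveState.from_memory_length(p, 2)
        s2 = sequential_update(s, 0.0, var_floor=1e-20)
        assert s2.params.var_rest >= 1e-20


class TestClassifyStream:
    def test_constant_rest_series(self):
        p = GmmParams(0.5, 0.5, 0.0, 10.0, 1.0, 1.0)
        res = classify_stream(np.zeros(500), p, L=1000)
        assert not res.labels.any()

    def test_step_series_switches_within_one_step(self):
        p = GmmParams(0.5, 0.5, 0.0, 10.0, 1.0, 1.0)
        x = np.concatenate([np.zeros(100), np.full(100, 10.0)])
        res = classify_stream(x, p, L=1000)
        assert not res.labels[:100].any()
        assert res.labels[100:].all()

    def test_theta_trace_between_running_means(self):
        rng = np.random.default_rng(9)
        x = _draw_mixture(rng, 5000)
        p = em_fit(x[:2000]).params
        res = classify_stream(x, p, L=500)
        assert np.all(res.theta_trace > 0.0)
        assert np.all(res.theta_trace < 6.0)

    def test_affine_invariance_of_classification(self):
        rng = np.random.default_rng(13)
        x = _draw_mixture(rng, 3000)
        p = em_fit(x[:1500]).params
        a, b = 2.5, -3.0
        p2 = GmmParams(
            p.w_rest, p.w_mov, a * p.mu_rest + b, a * p.mu_mov + b,
            a**2 * p.var_rest, a**2 * p.var_mov,
        )
        r1 = classify_stream(x, p, L=200)
        r2 = classify_stream(a * x + b, p2, L=200)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_batched_equals_scalar_path(self):
        rng = np.random.default_rng(21)
        x = _draw_mixture(rng, 400)
        p = em_fit(x).params
        single = classify_stream(x, p, L=100)
        s = AdaptiveState.from_memory_length(p, 100)
        labels = []
        for xi in x:
            labels.append(1 if xi >= s.theta else 0)
            s = sequential_update(s, float(xi))
        np.testing.assert_array_equal(single.labels, labels)
        assert s.params.mu_rest == pytest.approx(
            single.final_states[0].params.mu_rest, rel=1e-9
        )


class TestModelFiles:
    def test_roundtrip(self, tmp_path):
        models = {
            ("Biceps", "IAV"): GmmParams(0.6, 0.4, 1.0, 5.0, 0.25, 1.0),
            ("Triceps", "WL"): GmmParams(0.5, 0.5, 0.1, 2.0, 0.04, 0.2),
        }
        path = tmp_path / "models.txt"
        save_models(models, path, metadata={"event": "go-forward"})
        back = load_models(path)
        assert back == models
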