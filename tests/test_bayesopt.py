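import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from hrsnn.bayesopt import (DistributionPoint, GPSurrogate, KernelConfig,
                            SearchSpace, bo_loop, distribution_distance,
                            expected_improvement, gp_posterior, gram_matrix,
                            matern_value, matern_wasserstein_kernel,
                            sinkhorn_distance, wasserstein_1d)
from hrsnn.exceptions import SpecificationError
from hrsnn.lif_core import GammaSpec


def make_point(tau_e=20.0, tau_i=10.0, cv=0.0, lam=2.0, p_ir=0.3, ws=1.0):
    return DistributionPoint(
        tau_m_E=GammaSpec(tau_e, cv), tau_m_I=GammaSpec(tau_i, cv),
        A_plus=GammaSpec(5e-3, cv), A_minus=GammaSpec(5e-3, cv),
        tau_plus=GammaSpec(20.0, cv), tau_minus=GammaSpec(20.0, cv),
        lambda_conn=lam, P_IR=p_ir, W_scale=ws)


def random_point(rng):
    return SearchSpace().sample(rng)


class TestWasserstein1D:
    def test_identity(self):
        spec = GammaSpec(5.0, 0.4)
        assert wasserstein_1d(spec, spec) == pytest.approx(0.0, abs=1e-12)

    def test_point_masses(self):
        assert wasserstein_1d(GammaSpec(2.0, 0.0), GammaSpec(5.0, 0.0)) == 3.0

    def test_translation_equivariance_samples(self, rng):
        x = rng.gamma(2.0, 1.0, 500)
        assert wasserstein_1d(x, x + 0.7) == pytest.approx(0.7, abs=1e-9)

    def test_gamma_quadrature_against_quad(self):
        # independent oracle: integrate |F_X^{-1}(u) - F_Y^{-1}(u)| du by quad
        a = GammaSpec(10.0, 0.5)
        b = GammaSpec(14.0, 0.3)

        def integrand(u):
            return abs(stats.gamma.ppf(u, a.shape, scale=a.scale)
                       - stats.gamma.ppf(u, b.shape, scale=b.scale))

        expected, _ = integrate.quad(integrand, 0.0, 1.0, limit=200)
        assert wasserstein_1d(a, b) == pytest.approx(expected, rel=1e-3)

    def test_empty_sample_rejected(self):
        with pytest.raises(SpecificationError):
            wasserstein_1d(np.array([]), np.array([1.0]))


class TestSinkhorn:
    def test_self_distance_near_zero(self, rng):
        x = rng.normal(0, 1, 40)
        assert sinkhorn_distance(x, x, epsilon=0.05) <= 1e-6

    def test_symmetry(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(2, 1, 30)
        d1 = sinkhorn_distance(x, y, epsilon=0.05)
        d2 = sinkhorn_distance(y, x, epsilon=0.05)
        assert d1 == pytest.approx(d2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_close_to_exact_wasserstein(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.0, 1.0, 50)
        y = rng.normal(3.0, 1.5, 50)
        exact = stats.wasserstein_distance(x, y)
        approx = sinkhorn_distance(x, y, epsilon=0.01)
        assert approx == pytest.approx(exact, rel=0.02)

    def test_invalid_epsilon(self, rng):
        with pytest.raises(SpecificationError):
            sinkhorn_distance(rng.normal(size=5), rng.normal(size=5), epsilon=0.0)


class TestDistributionDistance:
    def test_identity(self):
        p = make_point()
        assert distribution_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c = (random_point(rng) for _ in range(3))
            dab = distribution_distance(a, b)
            dba = distribution_distance(b, a)
            assert dab == pytest.approx(dba, rel=1e-9)
            assert dab <= (distribution_distance(a, c)
                           + distribution_distance(c, b) + 1e-9)

    def test_point_mass_mean_shift(self):
        space = SearchSpace()
        p = make_point(tau_e=20.0)
        q = make_point(tau_e=23.0)
        expected = 3.0 / space.mean_width("tau_m_E")
        assert distribution_distance(p, q, space) == pytest.approx(expected)

    def test_joint_sinkhorn_mode(self):
        p = make_point(cv=0.2)
        q = make_point(cv=0.2, tau_e=30.0)
        d = distribution_distance(p, q, mode="joint_sinkhorn")
        assert d > 0
        assert distribution_distance(p, p, mode="joint_sinkhorn") == pytest.approx(
            0.0, abs=1e-6)


class TestMaternKernel:
    def test_zero_distance_gives_sigma2(self):
        cfg = KernelConfig(sigma2=2.5, kappa=1.0, rho=1.5)
        assert matern_value(0.0, cfg) == 2.5

    def test_rho_half_exponential(self):
        cfg = KernelConfig(sigma2=1.7, kappa=0.8, rho=0.5)
        for w in (0.1, 0.8, 2.0):
            assert matern_value(w, cfg) == pytest.approx(
                1.7 * math.exp(-w / 0.8), abs=1e-10)

    def test_rho_three_halves_closed_form(self):
        cfg = KernelConfig(sigma2=1.0, kappa=1.0, rho=1.5)
        expected = (1 + math.sqrt(3)) * math.exp(-math.sqrt(3))
        assert matern_value(1.0, cfg) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.4834, abs=1e-4)

    def test_decreasing_in_distance(self):
        cfg = KernelConfig(sigma2=1.0, kappa=1.0, rho=2.5)
        vals = [matern_value(w, cfg) for w in np.linspace(0, 5, 30)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(0 < v <= 1.0 + 1e-12 for v in vals)

    def test_generic_rho_matches_bessel_form(self):
        from scipy import special
        cfg = KernelConfig(sigma2=1.0, kappa=1.0, rho=1.7)
        w = 0.9
        z = math.sqrt(2 * 1.7) * w
        expected = 2 ** (1 - 1.7) / special.gamma(1.7) * z ** 1.7 * special.kv(1.7, z)
        assert matern_value(w, cfg) == pytest.approx(expected, rel=1e-10)


class TestGram:
    def test_single_point(self):
        cfg = KernelConfig(sigma2=2.0)
        g = gram_matrix([make_point()], cfg)
        assert g.shape == (1, 1)
        assert g[0, 0] == pytest.approx(2.0, rel=1e-6)

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        pts = [random_point(rng) for _ in range(8)]
        g = gram_matrix(pts, KernelConfig())
        np.testing.assert_allclose(g, g.T, atol=1e-12)

    def test_psd_random_sets(self):
        cfg = KernelConfig(sigma2=1.0, kappa=0.7, rho=1.5)
        rng = np.random.default_rng(11)
        for _ in range(10):
            pts = [random_point(rng) for _ in range(12)]
            g = gram_matrix(pts, cfg)
            assert np.linalg.eigvalsh(g).min() >= -1e-8


class TestGPPosterior:
    def make_surrogate(self, n=3, noise=0.0, cv=0.0):
        pts = [make_point(tau_e=te, cv=cv) for te in (12.0, 20.0, 33.0)][:n]
        y = np.array([1.0, -0.5, 2.0])[:n]
        return GPSurrogate(points=pts, values=y,
                           kernel=KernelConfig(sigma2=1.0, kappa=0.5, rho=0.5),
                           noise=noise, space=SearchSpace())

    def test_interpolates_training_points(self):
        s = self.make_surrogate()
        for p, yv in zip(s.points, s.values):
            mean, var = gp_posterior(s, p)
            assert mean == pytest.approx(yv, abs=1e-4)
            assert var <= 1e-6

    def test_prior_reversion_far_away(self):
        s = self.make_surrogate()
        far = make_point(tau_e=39.9, lam=7.9, p_ir=0.89, ws=4.9)
        far = DistributionPoint(
            tau_m_E=GammaSpec(39.9, 0.99), tau_m_I=GammaSpec(19.9, 0.99),
            A_plus=GammaSpec(1.9e-2, 0.99), A_minus=GammaSpec(1.9e-2, 0.99),
            tau_plus=GammaSpec(39.0, 0.99), tau_minus=GammaSpec(39.0, 0.99),
            lambda_conn=7.9, P_IR=0.89, W_scale=4.9)
        mean, var = gp_posterior(s, far)
        assert mean == pytest.approx(float(s.values.mean()), abs=0.05)
        assert var == pytest.approx(1.0, abs=0.05)

    def test_matches_explicit_solve(self):
        # independent oracle: hand-built 3x3 kernel system with the rho=1/2
        # exponential closed form
        s = self.make_surrogate()
        space = SearchSpace()
        q = make_point(tau_e=25.0)
        dist = np.array([[distribution_distance(a, b, space) for b in s.points]
                         for a in s.points])
        K = 1.0 * np.exp(-dist / 0.5)
        K[np.diag_indices_from(K)] += 1e-10  # same jitter the package applies
        k_star = np.array([math.exp(-distribution_distance(p, q, space) / 0.5)
                           for p in s.points])
        mu = float(s.values.mean())
        expected_mean = mu + k_star @ np.linalg.solve(K, s.values - mu)
        expected_var = 1.0 - k_star @ np.linalg.solve(K, k_star)
        mean, var = gp_posterior(s, q)
        assert mean == pytest.approx(expected_mean, abs=1e-10)
        assert var == pytest.approx(max(expected_var, 0.0), abs=1e-8)

    def test_variance_bounded_by_prior(self):
        s = self.make_surrogate(noise=0.1)
        rng = np.random.default_rng(5)
        for _ in range(10):
            _, var = gp_posterior(s, random_point(rng))
            assert var <= s.kernel.sigma2 + s.noise + 1e-9


class TestExpectedImprovement:
    def test_zero_sd_no_improvement(self):
        assert expected_improvement(1.0, 0.0, 2.0) == 0.0
        assert expected_improvement(2.0, 0.0, 1.0) == 1.0

    def test_mean_equals_best(self):
        s = 0.37
        assert expected_improvement(1.0, s, 1.0) == pytest.approx(
            s * stats.norm.pdf(0.0), rel=1e-12)
        assert stats.norm.pdf(0.0) == pytest.approx(0.39894, abs=1e-5)

    @pytest.mark.parametrize("seed", range(20))
    def test_monte_carlo_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mean = rng.uniform(-2, 2)
        sd = rng.uniform(0.2, 2.0)
        f_best = rng.uniform(-2, 2)
        draws = rng.normal(mean, sd, 1_000_000)
        mc = np.maximum(draws - f_best, 0.0).mean()
        assert expected_improvement(mean, sd, f_best) == pytest.approx(
            mc, rel=0.01, abs=1e-3)

    @settings(max_examples=60, deadline=None)
    @given(mean=st.floats(-5, 5), sd=st.floats(0, 3), f_best=st.floats(-5, 5))
    def test_nonnegative_property(self, mean, sd, f_best):
        assert expected_improvement(mean, sd, f_best) >= 0.0


class TestBOLoop:
    def frozen_space(self):
        # only the two membrane-time-constant means are free
        space = SearchSpace()
        space.cv_bounds = {k: (0.0, 0.0) for k in space.cv_bounds}
        space.mean_bounds = dict(space.mean_bounds)
        for k in ("A_plus", "A_minus", "tau_plus", "tau_minus"):
            space.mean_bounds[k] = (5e-3, 5e-3) if k.startswith("A") else (20.0, 20.0)
        space.scalar_bounds = {"lambda_conn": (2.0, 2.0), "P_IR": (0.3, 0.3),
                               "W_scale": (1.0, 1.0)}
        return space

    def test_best_so_far_monotone(self):
        space = self.frozen_space()
        target = make_point(tau_e=27.0, tau_i=8.0)

        def objective(p):
            return -distribution_distance(p, target, space)

        _, hist = bo_loop(objective, space, budget=20, n_init=6, seed=0)
        best = hist.best_so_far
        assert np.all(np.diff(best) >= 0)

    def test_deterministic(self):
        space = self.frozen_space()
        target = make_point(tau_e=27.0, tau_i=8.0)

        def objective(p):
            return -distribution_distance(p, target, space)

        _, h1 = bo_loop(objective, space, budget=15, n_init=5, seed=3)
        _, h2 = bo_loop(objective, space, budget=15, n_init=5, seed=3)
        assert h1.fitness == h2.fitness

    def test_recovers_target_within_5pct(self):
        # grid-search oracle for the optimum of the 2-free-parameter problem
        space = self.frozen_space()
        target = make_point(tau_e=27.0, tau_i=8.0)

        def objective(p):
            return -distribution_distance(p, target, space)

        te_grid = np.linspace(10, 40, 100)
        ti_grid = np.linspace(5, 20, 100)
        vals = np.array([[objective(make_point(tau_e=te, tau_i=ti))
                          for ti in ti_grid] for te in te_grid])
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        opt_te, opt_ti = te_grid[i], ti_grid[j]
        assert abs(opt_te - 27.0) < 0.5 and abs(opt_ti - 8.0) < 0.5

        best, hist = bo_loop(objective, space, budget=50, n_init=10, seed=1)
        assert abs(best.tau_m_E.mean - opt_te) <= 0.05 * 30.0
        assert abs(best.tau_m_I.mean - opt_ti) <= 0.05 * 15.0

    def test_objective_failure_tolerated(self):
        space = self.frozen_space()
        calls = {"n": 0}

        def objective(p):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return -abs(p.tau_m_E.mean - 20.0)

        best, hist = bo_loop(objective, space, budget=12, n_init=4, seed=0)
        assert len(hist.fitness) == 12

    def test_history_log_roundtrip(self, tmp_path):
        space = self.frozen_space()
        target = make_point(tau_e=27.0, tau_i=8.0)
        _, hist = bo_loop(lambda p: -distribution_distance(p, target, space),
                          space, budget=8, n_init=4, seed=0)
        path = tmp_path / "bo.log"
        hist.to_log(path)
        from hrsnn.bayesopt import BOHistory
        back = BOHistory.from_log(path)
        assert back.fitness == pytest.approx(hist.fitness)
        assert back.points[0].tau_m_E.mean == pytest.approx(
            hist.points[0].tau_m_E.mean)


class TestKernelOnPoints:
    def test_kernel_between_points_in_range(self):
        rng = np.random.default_rng(2)
        cfg = KernelConfig(sigma2=1.3)
        for _ in range(20):
            v = matern_wasserstein_kernel(random_point(rng), random_point(rng), cfg)
            assert 0 < v <= 1.3 + 1e-9
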