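"""VES functional machinery: gradients, masking, optimizers, orchestration."""

import numpy as np
import pytest

from localves.basis import build_gaussian_basis, build_polynomial_basis
from localves.dynamics import DynamicsConfig
from localves.engine import (
    Adam,
    AveragedSGD,
    BiasState,
    SampledAverages,
    VESConfig,
    adam_step,
    averaged_sgd_step,
    bias_energy_force,
    gradient_hessian,
    mask_uncovered,
    run_ves,
    sampled_averages,
    target_averages,
    uniform_target,
    update_well_tempered_target,
    well_tempered_target,
)
from localves.potentials import DoubleWell


@pytest.fixture()
def small_basis():
    return build_polynomial_basis((-3.0, 3.0), 2, "legendre")  # 3 functions


class TestBiasEnergyForce:
    def test_zero_coefficients(self, sym8_basis):
        bias = BiasState(sym8_basis)
        e, f = bias_energy_force(bias, 0.3)
        assert e == 0.0 and f[0] == 0.0

    def test_constant_only(self, sym8_basis):
        alpha = np.zeros(sym8_basis.size)
        alpha[0] = 2.5
        bias = BiasState(sym8_basis, alpha, alpha)
        e, f = bias_energy_force(bias, 1.234)
        assert e == pytest.approx(2.5) and f[0] == 0.0

    def test_zero_outside_interval(self, sym8_basis):
        alpha = np.ones(sym8_basis.size)
        bias = BiasState(sym8_basis, alpha, alpha)
        e, f = bias_energy_force(bias, 3.5)
        assert e == 0.0 and f[0] == 0.0

    def test_matches_brute_force_sum(self, sym8_basis, rng):
        alpha = rng.normal(size=sym8_basis.size)
        bias = BiasState(sym8_basis, alpha, alpha)
        for x in rng.uniform(-2.9, 2.9, 20):
            e, f = bias_energy_force(bias, x)
            vals, ders, _ = sym8_basis.evaluate(x)
            e_ref = sum(alpha[i] * vals[i] for i in range(sym8_basis.size))
            f_ref = -sum(
                alpha[i] * ders[i, 0] for i in range(sym8_basis.size)
            )
            assert e == pytest.approx(e_ref, rel=1e-12)
            assert f[0] == pytest.approx(f_ref, rel=1e-12)


class TestSampledAverages:
    def test_single_sample_is_exact(self, small_basis):
        s = np.array([0.77])
        out = sampled_averages(s, small_basis)
        vals, _, _ = small_basis.evaluate(0.77)
        np.testing.assert_allclose(out.mean_f, vals)
        np.testing.assert_allclose(out.mean_ff_diag, vals**2)

    def test_constant_function_statistics(self, small_basis, rng):
        out = sampled_averages(rng.uniform(-3, 3, 100), small_basis)
        assert out.mean_f[0] == 1.0 and out.coverage[0]

    def test_empty_batch_rejected(self, small_basis):
        with pytest.raises(ValueError):
            sampled_averages(np.array([]), small_basis)

    def test_uniform_batch_converges_to_quadrature(self, small_basis, rng):
        n = 20_000
        s = rng.uniform(-3, 3, n)
        out = sampled_averages(s, small_basis)
        target = uniform_target(small_basis.intervals, 2001)
        exact = target_averages(target, small_basis)
        se = np.sqrt(out.mean_ff_diag - out.mean_f**2) / np.sqrt(n)
        assert np.all(np.abs(out.mean_f - exact) <= 5 * se + 1e-12)


class TestTargetAverages:
    def test_constant_gives_one_for_any_normalized_target(self, small_basis):
        t = uniform_target(small_basis.intervals, 501)
        assert target_averages(t, small_basis)[0] == pytest.approx(1.0)

    def test_antisymmetric_function_zero_under_uniform(self, small_basis):
        # Legendre degree 1 is odd about the interval midpoint
        t = uniform_target(small_basis.intervals, 2001)
        assert target_averages(t, small_basis)[1] == pytest.approx(0.0, abs=1e-14)

    def test_quadrature_refinement_stable(self, small_basis):
        a = target_averages(uniform_target(small_basis.intervals, 20_001), small_basis)
        b = target_averages(uniform_target(small_basis.intervals, 40_001), small_basis)
        assert np.max(np.abs(a - b)) <= 1e-8

    def test_grid_interval_mismatch_rejected(self, small_basis):
        t = uniform_target([(-1.0, 1.0)], 101)
        with pytest.raises(ValueError):
            target_averages(t, small_basis)


class TestGradientHessian:
    def test_stationary_condition_gives_zero_gradient(self, small_basis):
        t = uniform_target(small_basis.intervals, 501)
        means = target_averages(t, small_basis)
        sampled = SampledAverages(means, means**2 + 0.1, np.ones(3, bool))
        grad, hess = gradient_hessian(sampled, means, beta=2.0)
        np.testing.assert_allclose(grad, 0.0)
        assert np.all(hess >= 0.0)

    def test_single_sample_zero_variance(self, small_basis):
        out = sampled_averages(np.array([0.3]), small_basis)
        _, hess = gradient_hessian(out, np.zeros(3), beta=2.0)
        np.testing.assert_allclose(hess, 0.0, atol=1e-15)

    def test_mismatched_lengths_rejected(self, small_basis):
        out = sampled_averages(np.array([0.3]), small_basis)
        with pytest.raises(ValueError):
            gradient_hessian(out, np.zeros(5), beta=2.0)

    def test_gradient_matches_finite_difference_of_functional(self, small_basis):
        """Central differences of the quadrature-computed functional
        Omega(alpha) agree with the analytic gradient to 1e-4 relative."""
        pot = DoubleWell()
        beta = 2.0
        x = np.linspace(-3, 3, 4001)
        w = np.full(len(x), x[1] - x[0])
        w[[0, -1]] /= 2
        u = pot.energy(x)
        vals, _, _ = small_basis.evaluate_batch(x)
        t = uniform_target(small_basis.intervals, len(x))
        p_means = target_averages(t, small_basis)

        def omega(alpha):
            v = vals @ alpha
            zb = np.log((w * np.exp(-beta * (u + v - u.min()))).sum())
            z0 = np.log((w * np.exp(-beta * (u - u.min()))).sum())
            return (zb - z0) / beta + p_means @ alpha

        def grad_quadrature(alpha):
            v = vals @ alpha
            rho = w * np.exp(-beta * (u + v - (u + v).min()))
            rho /= rho.sum()
            mean_f = vals.T @ rho
            sampled = SampledAverages(
                mean_f, (vals**2).T @ rho, np.ones(3, bool)
            )
            g, _ = gradient_hessian(sampled, p_means, beta)
            return g

        rng = np.random.default_rng(4)
        alpha = rng.normal(scale=0.5, size=3)
        g = grad_quadrature(alpha)
        h = 1e-5
        for i in range(3):
            e = np.zeros(3)
            e[i] = h
            fd = (omega(alpha + e) - omega(alpha - e)) / (2 * h)
            assert fd == pytest.approx(g[i], rel=1e-4, abs=1e-8)


class TestMasking:
    def test_all_covered_unchanged(self, rng):
        g = rng.normal(size=5)
        h = rng.uniform(size=5)
        g2, h2 = mask_uncovered(g, h, np.ones(5, bool))
        np.testing.assert_array_equal(g, g2)
        np.testing.assert_array_equal(h, h2)

    def test_none_covered_zeroed(self, rng):
        g2, h2 = mask_uncovered(rng.normal(size=4), rng.uniform(size=4),
                                np.zeros(4, bool))
        assert not g2.any() and not h2.any()

    def test_mixed_exactly_flagged_entries(self, rng):
        g = rng.normal(size=8)
        h = rng.uniform(size=8)
        cov = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=bool)
        g2, h2 = mask_uncovered(g, h, cov)
        np.testing.assert_array_equal(g2[cov], g[cov])
        np.testing.assert_array_equal(g2[~cov], 0.0)
        np.testing.assert_array_equal(h2[~cov], 0.0)


class TestOptimizers:
    def _quadratic(self):
        H = np.array([0.2, 1.0, 1.8])
        alpha_star = np.array([1.0, -2.0, 0.5])
        grad = lambda a: H * (a - alpha_star)  # noqa: E731
        return H, alpha_star, grad

    def test_averaged_sgd_fixed_point(self, small_basis):
        bias = BiasState(small_basis)
        opt = AveragedSGD(mu=0.5)
        opt.step(bias, np.zeros(3), np.ones(3))
        np.testing.assert_allclose(bias.alpha, 0.0)

    def test_averaged_sgd_first_step_is_minus_mu_grad(self, small_basis):
        bias = BiasState(small_basis)
        g = np.array([1.0, -2.0, 3.0])
        averaged_sgd_step(AveragedSGD(mu=0.5), bias, g, np.ones(3))
        np.testing.assert_allclose(bias.alpha, -0.5 * g)

    def test_averaged_sgd_converges_on_quadratic(self, small_basis):
        H, alpha_star, grad = self._quadratic()
        bias = BiasState(small_basis)
        opt = AveragedSGD(mu=0.5)
        omegas = []
        for _ in range(10_000):
            g = grad(bias.alpha_bar) + H * (bias.alpha - bias.alpha_bar)
            # the recursion consumes grad(alpha_bar) and H(alpha_bar) separately
            opt.step(bias, grad(bias.alpha_bar), H)
            omegas.append(
                0.5 * (H * (bias.alpha_bar - alpha_star) ** 2).sum()
            )
            if np.max(np.abs(bias.alpha - alpha_star)) < 1e-6:
                break
        assert np.max(np.abs(bias.alpha - alpha_star)) < 1e-6
        # convexity proxy: the functional never increases along the averages
        diffs = np.diff(np.asarray(omegas))
        assert np.all(diffs <= 1e-12)

    def test_adam_zero_gradient_no_move(self, small_basis):
        bias = BiasState(small_basis)
        adam_step(Adam(eta=0.005), bias, np.zeros(3))
        np.testing.assert_allclose(bias.alpha, 0.0)

    def test_adam_first_step_magnitude(self, small_basis):
        """With zero initial moments the first update is ~eta*sign(g)."""
        bias = BiasState(small_basis)
        g = np.array([0.3, -4.0, 0.001])
        eta = 0.005
        adam_step(Adam(eta=eta), bias, g)
        expect = -eta * g / (np.abs(g) + 1e-8 * np.sqrt(1 - 0.999))
        np.testing.assert_allclose(bias.alpha, expect, rtol=1e-3)

    def test_adam_converges_on_quadratic(self, small_basis):
        H, alpha_star, grad = self._quadratic()
        bias = BiasState(small_basis)
        opt = Adam(eta=0.005)
        for _ in range(100_000):
            opt.step(bias, grad(bias.alpha))
            if np.max(np.abs(bias.alpha - alpha_star)) < 1e-4:
                break
        assert np.max(np.abs(bias.alpha - alpha_star)) < 1e-4


class TestWellTemperedTarget:
    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            well_tempered_target([(-3.0, 3.0)], gamma=1.0)

    def test_huge_gamma_limit_is_uniform(self, sym8_basis):
        t = well_tempered_target([(-3.0, 3.0)], gamma=1e9, bins=501)
        alpha = np.zeros(sym8_basis.size)
        alpha[0] = 1.0
        alpha[3] = -2.0
        bias = BiasState(sym8_basis, alpha, alpha)
        t2 = update_well_tempered_target(t, bias, beta=2.0)
        p = np.asarray(t2.grid.values)
        assert np.max(np.abs(p / p.mean() - 1.0)) <= 1e-6

    def test_symmetric_fes_gives_symmetric_bimodal_target(self, small_basis):
        t = well_tempered_target([(-3.0, 3.0)], gamma=5.0, bins=501)
        # even bias (Legendre degree 2) -> even implied FES
        alpha = np.array([0.0, 0.0, -1.5])
        bias = BiasState(small_basis, alpha, alpha)
        t2 = update_well_tempered_target(t, bias, beta=2.0)
        p = np.asarray(t2.grid.values)
        np.testing.assert_allclose(p, p[::-1], atol=1e-10)
        assert t2.normalization_defect() <= 1e-10

    def test_uniform_target_passes_through(self, small_basis):
        t = uniform_target([(-3.0, 3.0)], 101)
        bias = BiasState(small_basis)
        assert update_well_tempered_target(t, bias, 2.0) is t


class TestRunVes:
    def _config(self, **kw):
        basis = build_gaussian_basis((-3.0, 3.0), 9)
        defaults = dict(
            potential=DoubleWell(),
            basis=basis,
            dynamics=DynamicsConfig(dt=0.005, friction=10.0, beta=2.0),
            target=uniform_target(basis.intervals, 501),
            optimizer=AveragedSGD(mu=0.5),
            n_steps=10_000,
            stride=500,
            fes_stride=5_000,
            seed=42,
            record_samples=True,
        )
        defaults.update(kw)
        return VESConfig(**defaults)

    def test_iteration_and_snapshot_counts(self):
        res = run_ves(self._config())
        assert res.n_iterations == 20           # 10^4 steps / stride 500
        assert len(res.snapshots) == 2          # every 5000 steps
        assert res.snapshots[-1][0] == 20

    def test_multiple_walkers_pool_samples(self):
        res = run_ves(self._config(n_steps=100, stride=10, fes_stride=100,
                                   n_walkers=25))
        # 25 walkers x stride 10 = 250 pooled samples per iteration
        assert res.n_iterations == 10
        assert len(res.cv_samples) == 10 * 250

    def test_deterministic_given_seed(self):
        r1 = run_ves(self._config(n_steps=5_000))
        r2 = run_ves(self._config(n_steps=5_000))
        np.testing.assert_array_equal(r1.bias.alpha_bar, r2.bias.alpha_bar)
        np.testing.assert_array_equal(r1.cv_samples, r2.cv_samples)

    def test_pooling_invariance_of_gradient(self, small_basis, rng):
        """One batch of 500 equals two concatenated batches of 250."""
        s = rng.uniform(-3, 3, 500)
        t = uniform_target(small_basis.intervals, 501)
        means = target_averages(t, small_basis)
        g1, h1 = gradient_hessian(
            sampled_averages(s, small_basis), means, 2.0
        )
        pooled = np.concatenate([s[:250], s[250:]])
        g2, h2 = gradient_hessian(
            sampled_averages(pooled, small_basis), means, 2.0
        )
        np.testing.assert_array_equal(g1, g2)
        np.testing.assert_array_equal(h1, h2)

    def test_masking_is_noop_when_all_sampled(self, rng):
        basis = build_gaussian_basis((-3.0, 3.0), 9)
        s = rng.uniform(-3, 3, 2000)  # dense coverage
        out = sampled_averages(s, basis)
        assert out.coverage.all()
        g = rng.normal(size=basis.size)
        h = rng.uniform(size=basis.size)
        g2, h2 = mask_uncovered(g, h, out.coverage)
        np.testing.assert_array_equal(g, g2)
        np.testing.assert_array_equal(h, h2)
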