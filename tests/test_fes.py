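"""FES estimators (direct and reweighted) and the performance metrics."""

import numpy as np
import pytest

from localves.basis import build_polynomial_basis
from localves.engine import BiasState, TargetDistribution, uniform_target
from localves.fes import (
    MetricConfig,
    WeightedSamples,
    fes_from_bias,
    free_energy_difference,
    halfspace,
    reweighted_fes,
    rms_error,
)
from localves.grid import FESGrid, regular_grid


@pytest.fixture()
def leg_basis():
    return build_polynomial_basis((-3.0, 3.0), 4, "legendre")


class TestFesFromBias:
    def test_uniform_target_gives_minus_v(self, leg_basis, rng):
        alpha = rng.normal(scale=0.3, size=leg_basis.size)
        bias = BiasState(leg_basis, alpha, alpha)
        t = uniform_target(leg_basis.intervals, 501)
        fes = fes_from_bias(bias, t, beta=2.0)
        vals, _, _ = leg_basis.evaluate_batch(fes.axes[0])
        V = vals @ alpha
        diff = np.asarray(fes.values) + V
        assert np.ptp(diff) <= 1e-10

    def test_constant_coefficient_shift_is_absorbed(self, leg_basis, rng):
        alpha = rng.normal(scale=0.3, size=leg_basis.size)
        bias1 = BiasState(leg_basis, alpha, alpha)
        alpha2 = alpha.copy()
        alpha2[0] += 5.0
        bias2 = BiasState(leg_basis, alpha2, alpha2)
        t = uniform_target(leg_basis.intervals, 301)
        f1 = fes_from_bias(bias1, t, 2.0)
        f2 = fes_from_bias(bias2, t, 2.0)
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-10)

    def test_well_tempered_self_consistency(self, leg_basis, rng):
        """With p ~ exp(beta*V/(gamma-1)), the recovered FES equals
        gamma/(gamma-1) * (-V) up to a constant (algebra of the
        stationary-point relation with a well-tempered target)."""
        beta, gamma = 2.0, 5.0
        alpha = rng.normal(scale=0.2, size=leg_basis.size)
        bias = BiasState(leg_basis, alpha, alpha)
        grid = regular_grid(leg_basis.intervals, 801)
        vals, _, _ = leg_basis.evaluate_batch(grid.axes[0])
        V = vals @ alpha
        logp = beta * V / (gamma - 1.0)
        p = np.exp(logp - logp.max())
        p /= (p * grid.trapezoid_weights()).sum()
        grid.values = p
        t = TargetDistribution(kind="well_tempered", grid=grid, gamma=gamma)
        fes = fes_from_bias(bias, t, beta)
        expect = gamma / (gamma - 1.0) * (-V)
        diff = np.asarray(fes.values) - expect
        assert np.ptp(diff) <= 1e-10

    def test_vanishing_target_rejected(self, leg_basis):
        bias = BiasState(leg_basis)
        grid = regular_grid(leg_basis.intervals, 101)
        p = np.ones(101)
        p[50] = 0.0
        grid.values = p / (p * grid.trapezoid_weights()).sum()
        t = TargetDistribution(kind="uniform", grid=grid)
        with pytest.raises(ValueError, match="vanishes"):
            fes_from_bias(bias, t, 2.0)


class TestReweightedFes:
    def test_zero_bias_equals_unweighted_kde(self, rng):
        pts = rng.normal(0.0, 0.6, 4000)
        grid = regular_grid([(-3.0, 3.0)], 301)
        f0 = reweighted_fes(
            WeightedSamples(pts, np.zeros(len(pts))), 1.0, grid, 0.1
        )
        f1 = reweighted_fes(
            WeightedSamples(pts, np.full(len(pts), 3.21)), 1.0, grid, 0.1
        )
        # constant bias cancels in the normalization
        np.testing.assert_allclose(f0.values, f1.values, atol=1e-9)

    def test_importance_sampling_identity(self, rng):
        """Samples from e^{-beta(F+V)} reweighted by e^{+beta V} recover F."""
        beta = 2.0
        grid = regular_grid([(-3.0, 3.0)], 401)
        x = grid.axes[0]
        F = 0.5 * (x**2 - 1.0) ** 2          # known double well
        V = -0.8 * F                          # partial compensating bias
        dens = np.exp(-beta * (F + V))
        dens /= dens.sum()
        n = 60_000
        idx = rng.choice(len(x), size=n, p=dens)
        pts = x[idx] + rng.uniform(-0.0075, 0.0075, n)  # de-discretize
        logw = beta * np.interp(pts, x, V)
        est = reweighted_fes(WeightedSamples(pts, logw), beta, grid, 0.05)
        # compare in the well-sampled region, shift-invariantly
        ref = FESGrid(axes=[x.copy()])
        ref.values = F - F.min()
        err = rms_error(est, ref, beta, MetricConfig(nu=6.0,
                                                     shift_region_threshold=3.0))
        # bootstrap the same statistic over resampled data sets
        boot = []
        for _ in range(20):
            sel = rng.integers(0, n, n)
            e = reweighted_fes(
                WeightedSamples(pts[sel], logw[sel]), beta, grid, 0.05
            )
            boot.append(rms_error(e, ref, beta,
                                  MetricConfig(nu=6.0, shift_region_threshold=3.0)))
        assert err <= np.mean(boot) + 3 * np.std(boot, ddof=1) + 0.05

    def test_transient_discard(self, rng):
        pts = np.concatenate([np.full(100, 2.9), rng.normal(0, 0.5, 2000)])
        grid = regular_grid([(-3.0, 3.0)], 201)
        full = reweighted_fes(WeightedSamples(pts, np.zeros(len(pts))),
                              1.0, grid, 0.1)
        cut = reweighted_fes(WeightedSamples(pts, np.zeros(len(pts))),
                             1.0, grid, 0.1, discard=100)
        ref = reweighted_fes(WeightedSamples(pts[100:], np.zeros(2000)),
                             1.0, grid, 0.1)
        np.testing.assert_allclose(cut.values, ref.values)
        assert not np.allclose(full.values, ref.values)

    def test_bandwidth_must_be_positive(self, rng):
        grid = regular_grid([(-1.0, 1.0)], 51)
        with pytest.raises(ValueError):
            reweighted_fes(WeightedSamples(np.zeros(5), np.zeros(5)),
                           1.0, grid, 0.0)


class TestRmsError:
    def _grids(self, ref_vals, fes_vals):
        ref = regular_grid([(0.0, 4.0)], 5)
        ref.values = np.asarray(ref_vals, dtype=float)
        fes = regular_grid([(0.0, 4.0)], 5)
        fes.values = np.asarray(fes_vals, dtype=float)
        return fes, ref

    def test_identical_surfaces_zero(self):
        fes, ref = self._grids([0, 1, 2, 3, 0], [0, 1, 2, 3, 0])
        assert rms_error(fes, ref, beta=1.0) == pytest.approx(0.0, abs=1e-14)

    def test_constant_offset_invisible(self):
        fes, ref = self._grids([0, 1, 2, 3, 0], np.array([0, 1, 2, 3, 0]) + 11.0)
        assert rms_error(fes, ref, beta=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_five_point_grid(self):
        """ref = (0,1,2,9,0) kT, fes = ref + (0.1,-0.1,0.1,5,-0.1), nu=8:
        the 9 kT point is excluded and the result is 0.1 kT."""
        ref_vals = np.array([0.0, 1.0, 2.0, 9.0, 0.0])
        fes, ref = self._grids(ref_vals, ref_vals + [0.1, -0.1, 0.1, 5.0, -0.1])
        err = rms_error(fes, ref, beta=1.0,
                        metric=MetricConfig(nu=8.0, shift_region_threshold=4.0))
        assert err == pytest.approx(0.1, abs=1e-12)

    def test_shift_invariance_both_arguments(self, rng):
        ref = regular_grid([(-2.0, 2.0)], 101)
        ref.values = (ref.axes[0] ** 2 - 1.0) ** 2
        fes = regular_grid([(-2.0, 2.0)], 101)
        fes.values = np.asarray(ref.values) + rng.normal(0, 0.2, 101)
        e0 = rms_error(fes, ref, 1.0)
        fes2 = regular_grid([(-2.0, 2.0)], 101)
        fes2.values = np.asarray(fes.values) + 123.4
        assert rms_error(fes2, ref, 1.0) == pytest.approx(e0, rel=1e-10)

    def test_mismatched_grids_rejected(self):
        fes, _ = self._grids([0, 1, 2, 3, 0], [0, 1, 2, 3, 0])
        other = regular_grid([(0.0, 5.0)], 5)
        other.values = np.zeros(5)
        with pytest.raises(ValueError):
            rms_error(fes, other, 1.0)


class TestFreeEnergyDifference:
    def test_symmetric_fes_zero(self):
        g = regular_grid([(-2.0, 2.0)], 401)
        g.values = (g.axes[0] ** 2 - 1.0) ** 2
        df = free_energy_difference(g, 2.0, halfspace(0, "<", 0.0),
                                    halfspace(0, ">", 0.0))
        assert df == pytest.approx(0.0, abs=1e-10)

    def test_constant_shift_invariant(self, rng):
        g = regular_grid([(-2.0, 2.0)], 201)
        g.values = rng.uniform(0, 3, 201)
        a, b = halfspace(0, "<", 0.3), halfspace(0, ">", 0.3)
        d0 = free_energy_difference(g, 1.5, a, b)
        g2 = regular_grid([(-2.0, 2.0)], 201)
        g2.values = np.asarray(g.values) + 7.0
        assert free_energy_difference(g2, 1.5, a, b) == pytest.approx(d0)

    def test_two_state_piecewise_constant(self):
        """F = 0 in A (x<0), 1 kT in B (x>0), equal widths -> -1 kT."""
        beta = 1.0
        g = regular_grid([(-1.0, 1.0)], 20_001)
        g.values = np.where(g.axes[0] > 0, 1.0, 0.0)
        df = free_energy_difference(g, beta, halfspace(0, "<", 0.0),
                                    halfspace(0, ">", 0.0))
        assert df == pytest.approx(-1.0, abs=1e-3)

    def test_wolfe_quapp_matches_direct_quadrature(self):
        """Eq-38-on-FES equals the Boltzmann ratio computed without the
        FES intermediary (independent double-quadrature oracle)."""
        from localves.potentials import get_potential, reference_fes

        pot = get_potential("wolfe_quapp")
        beta = 1.0
        ref = reference_fes(pot, beta, grid_bins=241)
        df = free_energy_difference(ref, beta, halfspace(1, "<", 0.0),
                                    halfspace(1, ">", 0.0))
        # direct ratio of Boltzmann integrals of U on the same lattice
        pts = ref.points
        u = pot.energy(pts)
        w = ref.trapezoid_weights().reshape(-1, order="F")
        bolt = np.exp(-beta * (u - u.min())) * w
        below = pts[:, 1] < 0
        above = pts[:, 1] > 0
        expect = -np.log(bolt[below].sum() / bolt[above].sum()) / beta
        assert df == pytest.approx(expect, abs=1e-10)

    def test_empty_region_rejected(self):
        g = regular_grid([(-1.0, 1.0)], 51)
        g.values = np.zeros(51)
        with pytest.raises(ValueError):
            free_energy_difference(g, 1.0, halfspace(0, "<", -5.0),
                                   halfspace(0, ">", 0.0))
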