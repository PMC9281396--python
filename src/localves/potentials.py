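"""Analytic benchmark potentials for single-particle Langevin sampling.

All energies are in reduced units with k_B = 1, so an inverse temperature
``beta`` converts energies to units of k_B*T directly.  Each potential
exposes its analytic gradient, which supplies the deterministic part of the
force in the dynamics module and is cross-checked against finite differences
in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import FESGrid, regular_grid

__all__ = [
    "PotentialSurface",
    "DoubleWell",
    "WolfeQuapp",
    "harmonic_wall",
    "reference_fes",
    "get_potential",
    "POTENTIALS",
]

# Rotated Wolfe-Quapp variant: the potential is rotated by -0.15*pi and the
# energy rescaled; both constants live here and nowhere else.
WOLFE_QUAPP_ROTATION_ANGLE = -0.15 * np.pi
WOLFE_QUAPP_ENERGY_SCALE = 2.0


@dataclass(frozen=True)
class PotentialSurface:
    """Base class for analytic model potentials.

    Subclasses implement :meth:`energy` and :meth:`gradient` as vectorized
    maps over points of shape ``(..., dim)`` (or scalars in one dimension).
    ``domain`` is the per-dimension closed interval on which the benchmark
    bias potentials are expanded; the potential itself is a total function
    on R^dim.
    """

    dim: int = field(init=False, default=1)
    domain: tuple[tuple[float, float], ...] = field(
        init=False, default=((-3.0, 3.0),)
    )

    def energy(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def force(self, x: np.ndarray) -> np.ndarray:
        return -self.gradient(x)


@dataclass(frozen=True)
class DoubleWell(PotentialSurface):
    """One-dimensional tilted double well.

    ``U(x) = a*(x^2 - x_min^2)^2 + tilt*x`` with two minima near +-2 inside
    [-3, 3], a unique global minimum on the left, and a barrier
    (saddle minus global minimum) of about 5 energy units, i.e. about
    10 k_B*T at the benchmark temperature T = 0.5.
    """

    a: float = 0.3125
    x_min: float = 2.0
    tilt: float = 0.1

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        return self.a * (x * x - self.x_min**2) ** 2 + self.tilt * x

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        return 4.0 * self.a * x * (x * x - self.x_min**2) + self.tilt


@dataclass(frozen=True)
class WolfeQuapp(PotentialSurface):
    """Two-dimensional Wolfe-Quapp potential, optionally rotated.

    The plain form is the canonical quartic
    ``U(x, y) = x^4 + y^4 - 2x^2 - 4y^2 + xy + 0.3x + 0.1y`` with two
    dominant minima separated by a high barrier along y.  The rotated
    variant evaluates the plain potential at coordinates rotated by
    ``WOLFE_QUAPP_ROTATION_ANGLE`` and scales the energy by
    ``WOLFE_QUAPP_ENERGY_SCALE``; it is used to benchmark biasing of a
    suboptimal collective variable (x only).
    """

    rotated: bool = False

    def __post_init__(self):
        object.__setattr__(self, "dim", 2)
        object.__setattr__(self, "domain", ((-3.0, 3.0), (-3.0, 3.0)))

    @staticmethod
    def _plain_energy(x, y):
        return (
            x**4 + y**4 - 2.0 * x * x - 4.0 * y * y + x * y + 0.3 * x + 0.1 * y
        )

    @staticmethod
    def _plain_gradient(x, y):
        gx = 4.0 * x**3 - 4.0 * x + y + 0.3
        gy = 4.0 * y**3 - 8.0 * y + x + 0.1
        return gx, gy

    def energy(self, p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        if self.rotated:
            c = np.cos(WOLFE_QUAPP_ROTATION_ANGLE)
            s = np.sin(WOLFE_QUAPP_ROTATION_ANGLE)
            x, y = c * x - s * y, s * x + c * y
            return WOLFE_QUAPP_ENERGY_SCALE * self._plain_energy(x, y)
        return self._plain_energy(x, y)

    def gradient(self, p):
        p = np.asarray(p, dtype=float)
        x, y = p[..., 0], p[..., 1]
        if self.rotated:
            c = np.cos(WOLFE_QUAPP_ROTATION_ANGLE)
            s = np.sin(WOLFE_QUAPP_ROTATION_ANGLE)
            xr, yr = c * x - s * y, s * x + c * y
            gx, gy = self._plain_gradient(xr, yr)
            gx, gy = c * gx + s * gy, -s * gx + c * gy
            gx = WOLFE_QUAPP_ENERGY_SCALE * gx
            gy = WOLFE_QUAPP_ENERGY_SCALE * gy
        else:
            gx, gy = self._plain_gradient(x, y)
        return np.stack([gx, gy], axis=-1)


def harmonic_wall(
    x: np.ndarray, kappa: float, x0: float, side: str = "upper"
) -> np.ndarray:
    """One-sided harmonic restraint ``kappa*(x - x0)^2`` beyond ``x0``.

    ``side="upper"`` restrains x > x0 (e.g. preventing further dissociation);
    ``side="lower"`` restrains x < x0.  The wall is continuous with a
    continuous first derivative at x0 and identically zero on the
    unrestrained side.
    """
    if kappa < 0:
        raise ValueError("wall force constant kappa must be non-negative")
    if side not in ("upper", "lower"):
        raise ValueError("side must be 'upper' or 'lower'")
    x = np.asarray(x, dtype=float)
    d = x - x0
    if side == "upper":
        d = np.maximum(d, 0.0)
    else:
        d = np.minimum(d, 0.0)
    return kappa * d * d


def reference_fes(
    potential: PotentialSurface,
    beta: float,
    grid_bins: Sequence[int] | int = 1000,
    marginalize: Sequence[int] = (),
    marginal_points: int = 2001,
    marginal_domain: tuple[float, float] | None = None,
) -> FESGrid:
    """Reference free-energy surface of a model potential by quadrature.

    Without marginalization the FES equals the potential itself up to an
    additive constant (the CV is the coordinate).  Marginalizing one
    dimension integrates the Boltzmann factor over it with the trapezoidal
    rule: ``F = -beta^-1 log int dy exp(-beta U)``.  A warning is raised if
    the integrand has not decayed at the marginalization boundary.

    The returned grid covers ``potential.domain`` and the values are shifted
    so the minimum is zero.
    """
    marginalize = tuple(marginalize)
    if len(marginalize) > 1:
        raise ValueError("at most one dimension may be marginalized")
    keep = [d for d in range(potential.dim) if d not in marginalize]
    if not keep:
        raise ValueError("cannot marginalize every dimension")
    bounds = [potential.domain[d] for d in keep]
    if np.isscalar(grid_bins):
        grid_bins = [int(grid_bins)] * len(keep)
    grid = regular_grid(bounds, grid_bins)

    if not marginalize:
        values = potential.energy(
            grid.points if potential.dim > 1 else grid.points[:, 0]
        )
        values = values.reshape(grid.shape, order="F")
    else:
        (mdim,) = marginalize
        lo, hi = marginal_domain or potential.domain[mdim]
        y = np.linspace(lo, hi, marginal_points)
        pts = np.empty(grid.points.shape[:1] + (len(y), potential.dim))
        for j, d in enumerate(keep):
            pts[..., d] = grid.points[:, j][:, None]
        pts[..., mdim] = y[None, :]
        u = potential.energy(pts)
        u0 = u.min()
        boltz = np.exp(-beta * (u - u0))
        edge = max(boltz[:, 0].max(), boltz[:, -1].max())
        if edge > 1e-10 * boltz.max():
            warnings.warn(
                "marginalization integrand not decayed at the domain edge: "
                f"boundary Boltzmann weight {edge:.3e} of max "
                f"{boltz.max():.3e}",
                RuntimeWarning,
                stacklevel=2,
            )
        integral = np.trapezoid(boltz, y, axis=1)
        values = (u0 - np.log(integral) / beta).reshape(grid.shape, order="F")

    values = values - values.min()
    grid.values = values
    grid.units = "k_B T" if beta == 1.0 else "energy"
    return grid


POTENTIALS = {
    "double_well": lambda: DoubleWell(),
    "wolfe_quapp": lambda: WolfeQuapp(rotated=False),
    "wolfe_quapp_rotated": lambda: WolfeQuapp(rotated=True),
}


def get_potential(name: str) -> PotentialSurface:
    """Look up a benchmark potential by its configuration name."""
    try:
        return POTENTIALS[name]()
    except KeyError:
        raise KeyError(
            f"unknown potential {name!r}; available: {sorted(POTENTIALS)}"
        ) from None
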