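"""Gaussian and cubic B-spline basis sets.

Both families place functions on evenly spaced centers ``mu_i = a + i*d``
with ``d = (b - a)/N``, ``i = -1..N``, so that one center lies beyond the
interval boundary to mitigate boundary bias (the bias force is zero outside
the interval by design, so outside-centered functions only contribute
inside).  With the constant function the total size is N + 3 for a given
user parameter N, keeping totals comparable across basis families.

Gaussians: ``f_i(x) = exp(-(x - mu_i)^2 / (2 sigma^2))`` with width
``sigma = 0.75 d`` by default (user-settable as a multiple of d).
Cubic B-splines: the peak-normalized piecewise cubic with fixed width
``sigma = d`` and compact support ``|x - mu_i| < 2 sigma``.
"""

from __future__ import annotations

import numpy as np

from .core import Basis1D

__all__ = ["GaussianBasis", "SplineBasis", "build_gaussian_basis",
           "build_spline_basis"]

#: footprint used for the coverage/masking flags of Gaussians, which have
#: no compact support: beyond 4 sigma the value is < 3.4e-4 of the peak.
GAUSSIAN_FOOTPRINT_SIGMAS = 4.0


class _CenteredBasis(Basis1D):
    def __init__(self, interval, N: int):
        super().__init__(interval)
        if N < 1:
            raise ValueError("center count parameter N must be >= 1")
        a, b = self.interval
        self.N = int(N)
        self.spacing = (b - a) / N
        self.centers = a + np.arange(-1, N + 1) * self.spacing
        self.size = 1 + len(self.centers)     # N + 3 including the constant


class GaussianBasis(_CenteredBasis):
    kind = "gaussian"

    def __init__(self, interval, N: int, sigma_factor: float = 0.75):
        if sigma_factor <= 0:
            raise ValueError("sigma_factor must be positive")
        super().__init__(interval, N)
        self.sigma = sigma_factor * self.spacing
        self.sigma_factor = float(sigma_factor)

    def _eval_nonconst(self, x, derivatives):
        z = (x[:, None] - self.centers[None, :]) / self.sigma
        vals = np.exp(-0.5 * z * z)
        ders = -(z / self.sigma) * vals if derivatives else None
        act = np.abs(z) <= GAUSSIAN_FOOTPRINT_SIGMAS
        return vals, ders, act


class SplineBasis(_CenteredBasis):
    """Peak-normalized cubic B-splines, support ``|x - mu| < 2 sigma``.

    With t = |x - mu|/sigma:
    ``f = 1 - 3 t^2 / 2 + 3 t^3 / 4`` for t <= 1,
    ``f = (2 - t)^3 / 4``            for 1 < t <= 2, else 0.
    Value and first derivative are continuous at t = 1 and t = 2.
    """

    kind = "bspline"

    def __init__(self, interval, N: int):
        super().__init__(interval, N)
        self.sigma = self.spacing

    def _eval_nonconst(self, x, derivatives):
        u = (x[:, None] - self.centers[None, :]) / self.sigma
        t = np.abs(u)
        inner = t <= 1.0
        outer = (t > 1.0) & (t < 2.0)
        vals = np.zeros_like(t)
        vals[inner] = 1.0 - 1.5 * t[inner] ** 2 + 0.75 * t[inner] ** 3
        vals[outer] = 0.25 * (2.0 - t[outer]) ** 3
        ders = None
        if derivatives:
            ders = np.zeros_like(t)
            ders[inner] = -3.0 * t[inner] + 2.25 * t[inner] ** 2
            ders[outer] = -0.75 * (2.0 - t[outer]) ** 2
            ders *= np.sign(u) / self.sigma
        act = t < 2.0
        return vals, ders, act


def build_gaussian_basis(
    interval, N: int, sigma_factor: float = 0.75
) -> GaussianBasis:
    """Gaussian basis: N + 3 functions total including the constant."""
    return GaussianBasis(interval, N, sigma_factor)


def build_spline_basis(interval, N: int) -> SplineBasis:
    """Cubic B-spline basis: N + 3 functions total including the constant."""
    return SplineBasis(interval, N)
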