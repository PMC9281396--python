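"""Chebyshev (first kind) and Legendre polynomial basis sets.

Both families are orthogonal on [-1, 1] and delocalized: every function is
non-zero on the whole interval except at isolated points.  On an interval
[a, b] the polynomials are composed with the affine map
``x = (2t - (a + b)) / (b - a)``.  The degree-0 polynomial is the constant
function, so a basis of order n has n + 1 functions in total.

Evaluation goes through numpy.polynomial (which implements the standard
three-term recursions); the recursion-vs-closed-form identity
``T_n(cos theta) = cos(n theta)`` is exercised in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import chebyshev as _cheb
from numpy.polynomial import legendre as _leg

from .core import Basis1D

__all__ = ["PolynomialBasis", "build_polynomial_basis"]

_FAMILIES = {
    "chebyshev": (_cheb.chebvander, _cheb.chebder, _cheb.chebval),
    "legendre": (_leg.legvander, _leg.legder, _leg.legval),
}


class PolynomialBasis(Basis1D):
    def __init__(self, interval, order: int, kind: str):
        if order < 1:
            raise ValueError("polynomial order must be >= 1")
        if kind not in _FAMILIES:
            raise ValueError(
                f"unknown polynomial kind {kind!r}; "
                f"choose from {sorted(_FAMILIES)}"
            )
        super().__init__(interval)
        self.kind = kind
        self.order = int(order)
        self.size = self.order + 1
        a, b = self.interval
        self._scale = 2.0 / (b - a)
        self._mid = 0.5 * (a + b)
        vander, der, val = _FAMILIES[kind]
        self._vander = vander
        # derivative of each degree-k polynomial, as coefficient vectors
        self._dcoef = []
        for k in range(self.size):
            c = np.zeros(self.size)
            c[k] = 1.0
            self._dcoef.append(der(c))
        self._val = val

    def _map(self, t):
        return self._scale * (t - self._mid)

    def _eval_nonconst(self, x, derivatives):
        z = self._map(x)
        vals = self._vander(z, self.order)[:, 1:]
        ders = None
        if derivatives:
            ders = np.stack(
                [self._val(z, self._dcoef[k]) for k in range(1, self.size)],
                axis=-1,
            ) * self._scale
        act = np.ones(vals.shape, dtype=bool)
        return vals, ders, act


def build_polynomial_basis(
    interval, order: int, kind: str
) -> PolynomialBasis:
    """Polynomial basis of degrees 0..order (order + 1 functions total)."""
    return PolynomialBasis(interval, order, kind)
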