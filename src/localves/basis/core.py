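"""Common interface for the bias-potential basis sets.

Every basis set is defined on a closed interval per collective variable and
contains one constant function (index 0).  Outside the interval all
non-constant functions — and hence the bias force — are zero by design.
``evaluate`` returns, for each basis function, its value, derivative(s) and
an "active" flag marking whether the point lies inside the function's
support footprint; the flags drive the gradient/Hessian masking of the
optimizer for localized bases.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BasisSet", "eval_basis"]


class BasisSet:
    """Abstract basis set over one or two collective variables."""

    kind: str = "abstract"
    dim: int = 1

    #: per-dimension closed interval [a, b]
    intervals: list[tuple[float, float]]
    #: total number of basis functions, including the constant
    size: int

    def evaluate_batch(
        self, x: np.ndarray, derivatives: bool = True
    ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
        """Evaluate all functions at many points.

        Parameters
        ----------
        x
            Points of shape ``(n,)`` (1D bases) or ``(n, dim)``.
        derivatives
            If False the derivative array is ``None`` (cheaper for the
            sampled averages, which only need values).

        Returns
        -------
        values : (n, size)
        derivs : (n, size, dim) or None
        active : (n, size) bool
        """
        raise NotImplementedError

    def evaluate(self, point) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Single-point evaluation; see :func:`eval_basis`."""
        p = np.atleast_1d(np.asarray(point, dtype=float))
        if not np.all(np.isfinite(p)):
            raise ValueError("basis evaluation at a non-finite point")
        if self.dim == 1:
            vals, ders, act = self.evaluate_batch(p.reshape(1))
        else:
            vals, ders, act = self.evaluate_batch(p.reshape(1, self.dim))
        return vals[0], ders[0], act[0]

    def grid_axes(self, bins: int) -> list[np.ndarray]:
        return [np.linspace(a, b, bins) for a, b in self.intervals]

    def __len__(self) -> int:
        return self.size

    def __repr__(self) -> str:
        iv = ", ".join(f"[{a:g}, {b:g}]" for a, b in self.intervals)
        return f"<{type(self).__name__} kind={self.kind} size={self.size} on {iv}>"


class Basis1D(BasisSet):
    """Helper base for one-dimensional sets: constant + localized/global."""

    dim = 1

    def __init__(self, interval: tuple[float, float]):
        a, b = float(interval[0]), float(interval[1])
        if not b > a:
            raise ValueError("interval must satisfy a < b")
        self.intervals = [(a, b)]

    @property
    def interval(self) -> tuple[float, float]:
        return self.intervals[0]

    # subclasses fill values/derivatives/support of the NON-constant part
    def _eval_nonconst(
        self, x: np.ndarray, derivatives: bool
    ) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
        raise NotImplementedError

    def evaluate_batch(self, x, derivatives=True):
        x = np.asarray(x, dtype=float).reshape(-1)
        n = len(x)
        a, b = self.interval
        inside = (x >= a) & (x <= b)
        vals = np.zeros((n, self.size))
        ders = np.zeros((n, self.size, 1)) if derivatives else None
        act = np.zeros((n, self.size), dtype=bool)
        vals[:, 0] = 1.0
        act[:, 0] = True
        if np.any(inside):
            v, d, s = self._eval_nonconst(x[inside], derivatives)
            vals[inside, 1:] = v
            if derivatives:
                ders[inside, 1:, 0] = d
            act[inside, 1:] = s
        return vals, ders, act


def eval_basis(basis: BasisSet, point):
    """Values, derivatives and active flags of every basis function.

    The constant function (index 0) evaluates to 1 with derivative 0 and is
    always active.  Points outside the basis interval return zero values and
    derivatives for all non-constant functions.
    """
    return basis.evaluate(point)
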