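"""Symlet (least-asymmetric Daubechies) scaling-function basis sets.

The scaling function phi of a SymN wavelet has no closed form; it is
defined implicitly by the two-scale refinement relation
``phi(x) = sqrt(2) * sum_k h_k phi(2x - k)`` with the 2N published filter
coefficients ``h_k`` and has support [0, 2N-1].  We tabulate phi and its
derivative on a dyadic grid with the vector cascade algorithm: the values
at the integers are the eigenvector of the characteristic two-scale matrix
``T[i, j] = sqrt(2) h_{2i-j}`` at eigenvalue 1 (eigenvalue 1/2 for the
derivative), after which the refinement relation doubles the resolution
exactly at each step.  Linear interpolation serves in-between values.

The basis used for the bias is a single level of father wavelets: integer
translates of phi under a dilation chosen such that, after discarding
translates whose maximum absolute value inside the bias interval falls
below 1% of the function's global maximum, exactly the requested number of
translates remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._symlet_filters import SYMLET_SCALING_FILTERS
from .core import Basis1D

__all__ = [
    "symlet_filters",
    "cascade_tabulate",
    "WaveletTable",
    "WaveletBasis",
    "build_wavelet_basis",
]

#: dyadic tabulation resolution: 2**11 points per unit of support
DEFAULT_LEVELS = 11


def symlet_filters(N: int) -> tuple[np.ndarray, np.ndarray]:
    """Scaling filter h and quadrature-mirror wavelet filter g of SymN.

    ``h`` has 2N entries summing to sqrt(2) and satisfying the double-shift
    orthogonality ``sum_k h_k h_{k+2m} = delta_{m0}``;
    ``g_k = (-1)^k h_{2N-1-k}``.
    """
    try:
        h = np.asarray(SYMLET_SCALING_FILTERS[int(N)], dtype=float)
    except KeyError:
        raise ValueError(
            f"unsupported symlet order N={N}; "
            f"supported orders: {sorted(SYMLET_SCALING_FILTERS)}"
        ) from None
    _check_filter(h)
    k = np.arange(len(h))
    g = (-1.0) ** k * h[::-1]
    return h, g


def _check_filter(h: np.ndarray) -> None:
    if abs(h.sum() - np.sqrt(2.0)) > 1e-12:
        raise ValueError("scaling filter does not sum to sqrt(2)")
    n = len(h)
    for m in range(1, n // 2):
        dot = float(h[: n - 2 * m] @ h[2 * m:])
        if abs(dot - (1.0 if m == 0 else 0.0)) > 1e-10:
            raise ValueError(
                f"double-shift orthogonality violated at shift 2m={2*m}: "
                f"{dot:.3e}"
            )
    if abs(h @ h - 1.0) > 1e-10:
        raise ValueError("scaling filter is not normalized")


@dataclass
class WaveletTable:
    """Tabulated father/mother wavelet of one symlet on a dyadic grid."""

    N: int
    h: np.ndarray
    g: np.ndarray
    levels: int                 # resolution = 2**levels points per unit
    x: np.ndarray               # dyadic grid on [0, 2N-1]
    phi: np.ndarray
    dphi: np.ndarray
    psi: np.ndarray
    dpsi: np.ndarray

    @property
    def support(self) -> float:
        return float(2 * self.N - 1)

    @property
    def resolution(self) -> int:
        return 2**self.levels

    def _interp(self, table: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Linear interpolation of a table over [0, support]; 0 outside."""
        res = self.resolution
        L = self.support
        y = np.asarray(y, dtype=float)
        inside = (y > 0.0) & (y < L)
        t = np.where(inside, y, 0.0) * res
        i = np.minimum(t.astype(np.int64), len(table) - 2)
        frac = t - i
        out = table[i] * (1.0 - frac) + table[i + 1] * frac
        return np.where(inside, out, 0.0)

    def phi_at(self, y):
        return self._interp(self.phi, y)

    def dphi_at(self, y):
        return self._interp(self.dphi, y)


def _eigen_start(T: np.ndarray, eigval: float) -> np.ndarray:
    """Real eigenvector of the two-scale matrix at the given eigenvalue."""
    w, v = np.linalg.eig(T)
    idx = np.argmin(np.abs(w - eigval))
    if abs(w[idx] - eigval) > 1e-8:
        raise ValueError(
            f"two-scale matrix has no eigenvalue {eigval} "
            f"(closest: {w[idx]:.6g}); invalid filter"
        )
    vec = np.real(v[:, idx])
    return vec


def cascade_tabulate(
    h: np.ndarray, points: int | None = None
) -> WaveletTable:
    """Tabulate phi, phi' (and psi, psi') from a scaling filter.

    ``points`` is the minimum total number of tabulation points over the
    support [0, 2N-1]; the dyadic resolution is rounded up to the next
    power of two per unit (default 2**11 per unit).  Values at dyadic
    points are exact (eigenvector start + exact refinement); derivatives
    come from the eigenvector at eigenvalue 1/2, not from differencing.
    """
    h = np.asarray(h, dtype=float)
    _check_filter(h)
    n = len(h)
    N = n // 2
    L = 2 * N - 1
    if points is None:
        levels = DEFAULT_LEVELS
    else:
        if points < 1000:
            raise ValueError("tabulation requires at least 1000 points")
        levels = max(1, int(np.ceil(np.log2(points / L))))

    # characteristic matrix on the interior integers 1..L-1
    i = np.arange(1, L)
    T = np.sqrt(2.0) * _filter_matrix(h, i)

    phi_int = _eigen_start(T, 1.0)
    phi_int = phi_int / phi_int.sum()          # partition of unity at integers
    dphi_int = _eigen_start(T, 0.5)
    scale = float(i @ dphi_int)                # sum_k k phi'(k) = -1
    if abs(scale) < 1e-12:
        raise ValueError("derivative eigenvector has vanishing first moment")
    dphi_int = dphi_int / (-scale)

    phi = _refine(h, phi_int, levels, deriv=False)
    dphi = _refine(h, dphi_int, levels, deriv=True)

    res = 2**levels
    x = np.arange(L * res + 1) / res

    # mother wavelet from the wavelet filter: psi(x) = sqrt2 sum g_k phi(2x-k)
    k = np.arange(n)
    g = (-1.0) ** k * h[::-1]
    psi = np.zeros_like(phi)
    dpsi = np.zeros_like(dphi)
    for kk in range(n):
        # phi(2x - k) on the dyadic grid: index 2*j - k*res at resolution res
        src = 2 * np.arange(len(x)) - kk * res
        ok = (src >= 0) & (src < len(phi))
        psi[ok] += np.sqrt(2.0) * g[kk] * phi[src[ok]]
        dpsi[ok] += 2.0 * np.sqrt(2.0) * g[kk] * dphi[src[ok]]

    return WaveletTable(
        N=N, h=h, g=g, levels=levels, x=x, phi=phi, dphi=dphi,
        psi=psi, dpsi=dpsi,
    )


def _filter_matrix(h: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Matrix M[r, c] = h[2*idx[r] - idx[c]] (zero outside the filter)."""
    n = len(h)
    M = np.zeros((len(idx), len(idx)))
    for r, ir in enumerate(idx):
        for c, ic in enumerate(idx):
            k = 2 * ir - ic
            if 0 <= k < n:
                M[r, c] = h[k]
    return M


def _refine(
    h: np.ndarray, start_int: np.ndarray, levels: int, deriv: bool
) -> np.ndarray:
    """Refine integer-grid values to 2**levels points/unit via two-scale."""
    n = len(h)
    L = n - 1
    factor = (2.0 if deriv else 1.0) * np.sqrt(2.0)
    # values at integers 0..L with zero endpoints
    v = np.zeros(L + 1)
    v[1:L] = start_int
    for j in range(levels):
        res = 2**j
        m = L * res
        new = np.zeros(2 * m + 1)
        new[::2] = v
        # odd points: x = (2i+1)/2**(j+1); phi(x) = f * sum h_k phi(2x - k)
        # 2x - k on the level-j grid has index (2i+1) - k*res
        odd = 2 * np.arange(m) + 1            # indices in the new array
        src_base = odd                         # = (2i+1) at level j indexing
        acc = np.zeros(m)
        for k in range(n):
            src = src_base - k * res
            ok = (src >= 0) & (src <= m)
            acc[ok] += h[k] * v[src[ok]]
        new[1::2] = factor * acc
        v = new
    return v


class WaveletBasis(Basis1D):
    """Single-level symlet father-wavelet basis on an interval."""

    kind = "wavelet"

    def __init__(
        self,
        interval: tuple[float, float],
        table: WaveletTable,
        shifts: np.ndarray,
        delta: float,
    ):
        super().__init__(interval)
        self.table = table
        self.shifts = np.asarray(shifts, dtype=np.int64)
        self.delta = float(delta)             # CV-space width of one shift unit
        self.size = 1 + len(self.shifts)
        self.N = table.N

    def _eval_nonconst(self, x, derivatives):
        a, _ = self.interval
        u = (x - a) / self.delta
        y = u[:, None] - self.shifts[None, :]
        vals = self.table.phi_at(y)
        ders = self.table.dphi_at(y) / self.delta if derivatives else None
        L = self.table.support
        act = (y > 0.0) & (y < L)
        return vals, ders, act


def _retained_shifts(
    table: WaveletTable, length: float, cutoff: float = 0.01
) -> np.ndarray:
    """Integer translates passing the relative-max cutoff on [0, length].

    Translate k of phi lives on [k, k + support]; it is retained when its
    maximum absolute value inside the window [0, length] is at least
    ``cutoff`` times its global maximum absolute value.
    """
    L = table.support
    res = table.resolution
    gmax = np.abs(table.phi).max()
    keep = []
    for k in range(-int(np.ceil(L)) + 1, int(np.floor(length)) + 1):
        y0 = max(0.0, -k)
        y1 = min(L, length - k)
        if y1 <= y0:
            continue
        i0 = int(np.ceil(y0 * res))
        i1 = int(np.floor(y1 * res)) + 1
        if i1 <= i0:
            continue
        if np.abs(table.phi[i0:i1]).max() >= cutoff * gmax:
            keep.append(k)
    return np.asarray(keep, dtype=np.int64)


def build_wavelet_basis(
    interval: tuple[float, float],
    size: int,
    N: int = 8,
    points: int | None = None,
    cutoff: float = 0.01,
) -> WaveletBasis:
    """Symlet basis with exactly ``size`` functions (constant included).

    The dilation is found by bisection on the interval length measured in
    shift units: the retained-translate count is a non-decreasing step
    function of that length, and we pick the midpoint of the plateau on
    which the count equals ``size - 1``.  If no dilation yields the
    requested count (the count jumps past it), an error reports the
    achievable neighboring counts.
    """
    if size < 2:
        raise ValueError("need at least the constant plus one wavelet")
    h, _ = symlet_filters(N)
    table = cascade_tabulate(h, points)
    target = size - 1
    L = table.support

    def count(length: float) -> int:
        return len(_retained_shifts(table, length, cutoff))

    lo, hi = 1e-6, float(target + 2 * L)
    if count(hi) < target:
        raise ValueError("requested basis size unreachable")  # pragma: no cover

    def first_length_with(c: int) -> float:
        a_, b_ = lo, hi
        for _ in range(80):
            mid = 0.5 * (a_ + b_)
            if count(mid) >= c:
                b_ = mid
            else:
                a_ = mid
        return b_

    t0 = first_length_with(target)
    t1 = first_length_with(target + 1)
    length = 0.5 * (t0 + t1)
    got = count(length)
    if got != target:
        raise ValueError(
            f"no dilation yields {target} retained translates for Sym{N} on "
            f"{interval}; achievable neighboring counts: "
            f"{count(t0 * (1 + 1e-9))} and {got}"
        )
    a, b = float(interval[0]), float(interval[1])
    delta = (b - a) / length
    shifts = _retained_shifts(table, length, cutoff)
    return WaveletBasis(interval, table, shifts, delta)
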