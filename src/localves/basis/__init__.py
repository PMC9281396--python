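"""Basis sets for the linear bias-potential expansion.

Five families are available — symlet wavelets, Gaussians, cubic B-splines,
Chebyshev and Legendre polynomials — each including one constant function,
plus tensor products for two-dimensional biases.  ``build_basis`` maps a
declarative configuration block onto a concrete basis set.
"""

from __future__ import annotations

from .core import BasisSet, eval_basis
from .localized import (
    GaussianBasis,
    SplineBasis,
    build_gaussian_basis,
    build_spline_basis,
)
from .polynomials import PolynomialBasis, build_polynomial_basis
from .tensor import TensorBasis, tensor_basis
from .wavelets import (
    WaveletBasis,
    WaveletTable,
    build_wavelet_basis,
    cascade_tabulate,
    symlet_filters,
)

__all__ = [
    "BasisSet",
    "GaussianBasis",
    "SplineBasis",
    "PolynomialBasis",
    "TensorBasis",
    "WaveletBasis",
    "WaveletTable",
    "eval_basis",
    "symlet_filters",
    "cascade_tabulate",
    "build_wavelet_basis",
    "build_gaussian_basis",
    "build_spline_basis",
    "build_polynomial_basis",
    "tensor_basis",
    "build_basis",
]


def build_basis(block: dict) -> BasisSet:
    """Construct a 1D basis from a configuration block.

    Expected keys: ``kind`` (wavelet | gaussian | bspline | chebyshev |
    legendre), ``interval`` ([a, b]), ``size`` (total including the
    constant), and family extras: ``order`` (symlet N, default 8) and
    ``sigma_factor`` (Gaussians, default 0.75).
    """
    kind = block["kind"]
    interval = tuple(block["interval"])
    size = int(block["size"])
    if kind == "wavelet":
        return build_wavelet_basis(interval, size, N=int(block.get("order", 8)))
    if kind == "gaussian":
        return build_gaussian_basis(
            interval, size - 3, sigma_factor=float(block.get("sigma_factor", 0.75))
        )
    if kind == "bspline":
        return build_spline_basis(interval, size - 3)
    if kind in ("chebyshev", "legendre"):
        return build_polynomial_basis(interval, size - 1, kind)
    raise ValueError(f"unknown basis kind {kind!r}")
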