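"""Tensor products of one-dimensional basis sets for 2D bias potentials.

The two-dimensional functions are all pairwise products
``f_ij(s1, s2) = g_i(s1) * h_j(s2)`` with partial derivatives by the
product rule.  The product of the two constants is the 2D constant and
sits at index 0 in the flattened ordering (first factor fastest would put
it there either way; we flatten with the SECOND factor fastest, i.e.
index = i * size2 + j, so (0, 0) -> 0).
"""

from __future__ import annotations

import numpy as np

from .core import BasisSet

__all__ = ["TensorBasis", "tensor_basis"]


class TensorBasis(BasisSet):
    kind = "tensor"
    dim = 2

    def __init__(self, b1: BasisSet, b2: BasisSet):
        if b1.dim != 1 or b2.dim != 1:
            raise ValueError("tensor products require one-dimensional factors")
        self.factors = (b1, b2)
        self.intervals = [b1.intervals[0], b2.intervals[0]]
        self.size = b1.size * b2.size

    def evaluate_batch(self, x, derivatives=True):
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != 2:
            raise ValueError("tensor basis expects points of shape (n, 2)")
        b1, b2 = self.factors
        v1, d1, a1 = b1.evaluate_batch(x[:, 0], derivatives)
        v2, d2, a2 = b2.evaluate_batch(x[:, 1], derivatives)
        n = x.shape[0]
        vals = (v1[:, :, None] * v2[:, None, :]).reshape(n, self.size)
        act = (a1[:, :, None] & a2[:, None, :]).reshape(n, self.size)
        ders = None
        if derivatives:
            ders = np.empty((n, self.size, 2))
            ders[:, :, 0] = (
                d1[:, :, 0][:, :, None] * v2[:, None, :]
            ).reshape(n, self.size)
            ders[:, :, 1] = (
                v1[:, :, None] * d2[:, :, 0][:, None, :]
            ).reshape(n, self.size)
        return vals, ders, act


def tensor_basis(b1: BasisSet, b2: BasisSet) -> TensorBasis:
    """All pairwise products of two 1D basis sets (size = M1 * M2)."""
    return TensorBasis(b1, b2)
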