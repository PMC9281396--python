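"""Regular CV-space grids and the plain-text grid file format.

The text format follows community grid-file conventions ('#' comment
headers declaring the fields and the per-dimension min/max/bins, one row
per grid point) so files can be plotted with standard tools.  Row order is
C-like with the FIRST CV as the fastest-running index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["FESGrid", "regular_grid", "write_grid", "read_grid"]


@dataclass
class FESGrid:
    """Values (e.g. a free energy) on a regular CV-space lattice.

    Values carry an arbitrary additive constant; comparisons must be made
    shift-invariantly (see :func:`localves.fes.rms_error`).  ``axes`` holds
    the per-dimension coordinate vectors (strictly increasing);
    ``values`` has shape ``tuple(len(ax) for ax in axes)``.
    """

    axes: list[np.ndarray]
    values: np.ndarray | None = None
    units: str = "energy"
    fields: list[str] = field(default_factory=list)

    def __post_init__(self):
        for ax in self.axes:
            if len(ax) < 2 or np.any(np.diff(ax) <= 0):
                raise ValueError("grid axes must be strictly increasing")
        if not self.fields:
            self.fields = [f"cv{i+1}" for i in range(self.dim)] + ["value"]

    @property
    def dim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(ax) for ax in self.axes)

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [(float(ax[0]), float(ax[-1])) for ax in self.axes]

    @property
    def points(self) -> np.ndarray:
        """All grid points, shape (n_points, dim), first CV fastest."""
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([m.reshape(-1, order="F") for m in mesh], axis=-1)

    def flat_values(self) -> np.ndarray:
        """Values in the same point order as :attr:`points`."""
        return np.asarray(self.values).reshape(-1, order="F")

    def trapezoid_weights(self) -> np.ndarray:
        """Separable trapezoidal quadrature weights, shaped like values."""
        w = np.ones(self.shape)
        for d, ax in enumerate(self.axes):
            wd = np.empty(len(ax))
            wd[1:-1] = (ax[2:] - ax[:-2]) / 2.0
            wd[0] = (ax[1] - ax[0]) / 2.0
            wd[-1] = (ax[-1] - ax[-2]) / 2.0
            shape = [1] * self.dim
            shape[d] = len(ax)
            w = w * wd.reshape(shape)
        return w


def regular_grid(
    bounds: Sequence[tuple[float, float]], bins: Sequence[int] | int
) -> FESGrid:
    """Uniform grid with ``bins`` points per dimension (inclusive ends)."""
    if np.isscalar(bins):
        bins = [int(bins)] * len(bounds)
    axes = [
        np.linspace(lo, hi, int(n)) for (lo, hi), n in zip(bounds, bins)
    ]
    return FESGrid(axes=axes)


def write_grid(grid: FESGrid, path: str | Path) -> None:
    """Write a grid to the text format (12+ significant digits)."""
    if grid.values is None:
        raise ValueError("grid has no values to write")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# FIELDS " + " ".join(grid.fields) + "\n")
        fh.write(f"# UNITS {grid.units}\n")
        for d, ax in enumerate(grid.axes):
            fh.write(
                f"# SET min_{grid.fields[d]} {ax[0]:.17g}\n"
                f"# SET max_{grid.fields[d]} {ax[-1]:.17g}\n"
                f"# SET nbins_{grid.fields[d]} {len(ax)}\n"
                f"# SET periodic_{grid.fields[d]} false\n"
            )
        pts = grid.points
        vals = grid.flat_values()
        for p, v in zip(pts, vals):
            fh.write(
                " ".join(f"{c:.17g}" for c in p) + f" {v:.17g}\n"
            )


def read_grid(path: str | Path) -> FESGrid:
    """Read a grid file written by :func:`write_grid`.

    Malformed headers, inconsistent row counts and non-monotone coordinates
    raise ``ValueError`` naming the offending line or count.
    """
    path = Path(path)
    fields: list[str] = []
    units = "energy"
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                tok = line[1:].split()
                if not tok:
                    continue
                if tok[0] == "FIELDS":
                    fields = tok[1:]
                elif tok[0] == "UNITS":
                    units = " ".join(tok[1:])
                elif tok[0] == "SET" and len(tok) >= 3:
                    meta[tok[1]] = tok[2]
                continue
            try:
                rows.append([float(t) for t in line.split()])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: malformed data row {line!r}"
                ) from None
    if not fields:
        raise ValueError(f"{path}: missing '# FIELDS' header")
    dim = len(fields) - 1
    axes = []
    for d in range(dim):
        name = fields[d]
        try:
            lo = float(meta[f"min_{name}"])
            hi = float(meta[f"max_{name}"])
            n = int(meta[f"nbins_{name}"])
        except KeyError as exc:
            raise ValueError(
                f"{path}: missing header entry {exc.args[0]!r}"
            ) from None
        axes.append(np.linspace(lo, hi, n))
    expected = int(np.prod([len(ax) for ax in axes]))
    if len(rows) != expected:
        raise ValueError(
            f"{path}: expected {expected} data rows, found {len(rows)}"
        )
    data = np.asarray(rows)
    # verify the stored coordinates match the declared lattice
    grid = FESGrid(axes=axes, units=units, fields=fields)
    if not np.allclose(data[:, :dim], grid.points, atol=1e-9):
        raise ValueError(
            f"{path}: row coordinates do not match the declared grid "
            "(expected first CV fastest)"
        )
    grid.values = data[:, dim].reshape(grid.shape, order="F")
    return grid
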