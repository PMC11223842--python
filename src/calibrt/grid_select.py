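"""Gridding and non-maximal suppression of the calibration point cloud.

The point cloud on the library/measured-RT plane is binned on an equal-width
grid (100x100 by default).  Keeping only the highest-count cell of every
occupied row and column thins the cloud to at most ``size_x + size_y`` cells
regardless of how many raw points went in, which is what makes the
downstream path search independent of the data size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import CalibrationPoints
from .exceptions import DegenerateRangeError

DEFAULT_GRID_SIZE = 100


@dataclass(frozen=True)
class GridSpec:
    """Equal-width binning of both RT axes over the data range.

    Bins are half-open ``[edge_i, edge_{i+1})`` except the last, which is
    closed so the maximum falls in the top cell (standard histogram rule).
    """

    size_x: int
    size_y: int
    x_edges: np.ndarray
    y_edges: np.ndarray

    def __post_init__(self) -> None:
        if self.size_x < 2 or self.size_y < 2:
            raise ValueError("grid must have at least 2 cells per axis")
        for edges, size in ((self.x_edges, self.size_x), (self.y_edges, self.size_y)):
            e = np.asarray(edges, dtype=float)
            if e.size != size + 1 or not (np.diff(e) > 0).all():
                raise ValueError("edges must be strictly increasing with size+1 entries")

    @classmethod
    def from_points(
        cls, points: CalibrationPoints, size_x: int = DEFAULT_GRID_SIZE, size_y: int | None = None
    ) -> "GridSpec":
        if size_y is None:
            size_y = size_x
        x, y = points.library_rt, points.measured_rt
        if x.min() == x.max() or y.min() == y.max():
            raise DegenerateRangeError(
                "zero range in one RT dimension; grid-based calibration is not applicable"
            )
        return cls(
            size_x,
            size_y,
            np.linspace(x.min(), x.max(), size_x + 1),
            np.linspace(y.min(), y.max(), size_y + 1),
        )


@dataclass(frozen=True)
class GridSummary:
    """Per-cell point counts plus the retained cell set after suppression.

    ``counts`` is indexed ``[iy, ix]``; ``retained`` holds ``(ix, iy)`` pairs
    and is ``None`` until :func:`nonmax_suppress` has run.
    """

    spec: GridSpec
    counts: np.ndarray
    retained: frozenset | None = None

    def cell_center(self, ix: int, iy: int) -> tuple[float, float]:
        xe, ye = self.spec.x_edges, self.spec.y_edges
        return (0.5 * (xe[ix] + xe[ix + 1]), 0.5 * (ye[iy] + ye[iy + 1]))


def grid_count(points: CalibrationPoints, spec: GridSpec) -> GridSummary:
    """Count points per grid cell; the total count is conserved."""
    hist, _, _ = np.histogram2d(
        points.library_rt, points.measured_rt, bins=[spec.x_edges, spec.y_edges]
    )
    counts = hist.T.astype(np.int64)  # rows are y, columns are x
    assert counts.sum() == points.n
    return GridSummary(spec=spec, counts=counts)


def nonmax_suppress(summary: GridSummary) -> GridSummary:
    """Retain the maximum-count cell of every occupied row and column.

    The retained set is the union of row-wise and column-wise maxima; ties go
    to the lowest index, and all-zero rows/columns contribute nothing.
    """
    counts = summary.counts
    retained: set[tuple[int, int]] = set()
    row_max = counts.max(axis=1)
    for iy in np.nonzero(row_max > 0)[0]:
        retained.add((int(np.argmax(counts[iy, :])), int(iy)))
    col_max = counts.max(axis=0)
    for ix in np.nonzero(col_max > 0)[0]:
        retained.add((int(ix), int(np.argmax(counts[:, ix]))))
    return GridSummary(spec=summary.spec, counts=counts, retained=frozenset(retained))
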