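"""Georeferenced raster grid: the carrier for every layer in the pipeline.

A :class:`Grid` is a rectangular array of cell values in a projected planar
coordinate system (meters).  ``(origin_x, origin_y)`` is the *top-left corner*
of the raster, rows increase southwards, and the center of cell ``(row, col)``
sits at ``(origin_x + (col + 0.5) * cell, origin_y - (row + 0.5) * cell)``.
Missing values are carried as NaN in memory; a ``nodata`` sentinel is only
used when grids are serialized to text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class GridAlignmentError(ValueError):
    """Raised when an operation mixes grids with different georeferences."""


@dataclass
class Grid:
    values: np.ndarray
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2D array")
        if not self.cell > 0:
            raise ValueError("cell size must be positive")

    # -- basic geometry -----------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the raster footprint."""
        return (
            self.origin_x,
            self.origin_y - self.nrows * self.cell,
            self.origin_x + self.ncols * self.cell,
            self.origin_y,
        )

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.ncols) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        return self.origin_y - (np.arange(self.nrows) + 0.5) * self.cell

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of all cell-center coordinates."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    # -- point <-> cell -----------------------------------------------------

    def cell_at(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing point(s) (x, y).

        Cells are half-open: a point exactly on a shared vertical edge belongs
        to the cell on the right, on a shared horizontal edge to the cell
        below.  No bounds check is performed; see :meth:`contains`.
        """
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.cell)
        return row.astype(int), col.astype(int)

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def sample(self, x, y) -> np.ndarray:
        """Value of the cell containing each point; NaN outside the extent."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        out = np.full(x.shape, np.nan)
        inside = self.contains(x, y)
        row, col = self.cell_at(x[inside], y[inside])
        out[inside] = self.values[row, col]
        return out

    # -- construction helpers ----------------------------------------------

    def like(self, values: np.ndarray) -> "Grid":
        """New grid sharing this grid's georeference."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValueError(
                f"shape {values.shape} does not match grid {self.shape}"
            )
        return Grid(values, self.origin_x, self.origin_y, self.cell, self.nodata)

    def same_georef(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell - other.cell) <= tol
        )

    def require_aligned(self, other: "Grid") -> None:
        if not self.same_georef(other):
            raise GridAlignmentError(
                "grids are not aligned (shape/origin/cell mismatch)"
            )

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def aligned(*grids: Grid) -> None:
    """Raise GridAlignmentError unless all grids share one georeference."""
    first = grids[0]
    for g in grids[1:]:
        first.require_aligned(g)
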