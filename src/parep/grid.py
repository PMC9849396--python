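"""Planar raster lattice shared by all rasters and masks in an analysis.

All geometry lives in planar kilometre coordinates on an equal-area grid:
no CRS, no latitude correction. Real-data inputs are expected to be
pre-projected to an equal-area system before ingestion. Arrays are indexed
``[row, col]`` with row 0 at the *bottom* (y increases with row index), so
raster axes agree with plot axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: default cell area, km^2 (≈ the 5 km² working resolution of tropical-Andes
#: distribution modelling this package is aimed at)
DEFAULT_CELL_AREA_KM2 = 5.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular grid of congruent square cells.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; both must be positive.
    cell_side
        Cell edge length in km. Defaults to √5 km so that the cell area is
        the package-wide default of 5 km².
    origin_x, origin_y
        Planar coordinates (km) of the lower-left corner of cell
        ``[0, 0]``.
    """

    n_rows: int
    n_cols: int
    cell_side: float = field(default=math.sqrt(DEFAULT_CELL_AREA_KM2))
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not (self.cell_side > 0 and math.isfinite(self.cell_side)):
            raise ValueError(f"cell_side must be positive, got {self.cell_side}")

    @property
    def cell_area_km2(self) -> float:
        return self.cell_side**2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def width(self) -> float:
        return self.n_cols * self.cell_side

    @property
    def height(self) -> float:
        return self.n_rows * self.cell_side

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the full grid extent."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.width,
            self.origin_y + self.height,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat arrays of cell-center x and y, in row-major cell order."""
        x = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_side
        y = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_side
        cx, cy = np.meshgrid(x, y)
        return cx.ravel(), cy.ravel()

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if off-grid."""
        col = int(np.floor((x - self.origin_x) / self.cell_side))
        row = int(np.floor((y - self.origin_y) / self.cell_side))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) lies outside the grid")
        return row, col

    def points_to_cells(self, xy: np.ndarray) -> np.ndarray:
        """Vectorised point→(row, col) lookup for an (n, 2) array."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        cols = np.floor((xy[:, 0] - self.origin_x) / self.cell_side).astype(int)
        rows = np.floor((xy[:, 1] - self.origin_y) / self.cell_side).astype(int)
        bad = (rows < 0) | (rows >= self.n_rows) | (cols < 0) | (cols >= self.n_cols)
        if bad.any():
            i = int(np.argmax(bad))
            raise ValueError(
                f"point ({xy[i, 0]}, {xy[i, 1]}) lies outside the grid"
            )
        return np.column_stack([rows, cols])

    def same_geometry(self, other: "GridSpec", rtol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.cell_side, other.cell_side, rel_tol=rtol)
            and math.isclose(self.origin_x, other.origin_x, abs_tol=rtol)
            and math.isclose(self.origin_y, other.origin_y, abs_tol=rtol)
        )


def require_same_grid(a: GridSpec, b: GridSpec) -> None:
    if not a.same_geometry(b):
        raise ValueError(f"grid mismatch: {a} vs {b}")
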