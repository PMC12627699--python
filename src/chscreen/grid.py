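"""The latitude/longitude template grid all layers align to.

The screening layer is an equiangular (plate carree) raster in geographic
WGS 84 coordinates.  Row 0 is the northernmost row and column 0 the
westernmost column.  Cell (r, c) covers the half-open box

    [west + c*s, west + (c+1)*s)  x  (north - (r+1)*s, north - r*s]

with ``s`` the cell size in degrees: a point on a shared vertical edge
belongs to the cell to its east, a point on a shared horizontal edge to the
cell to its south's northern neighbour (top edge closed).  The outer extent
boundary is closed on all sides, so points on the east/south rim are
assigned to the last column/row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import box

from .errors import GridAlignmentError, GridError, PointOutsideExtentError

#: default resolution of the published layers: 30 arcseconds
CELL_30_ARCSEC = 1.0 / 120.0

_REL_TOL = 1e-9


@dataclass(frozen=True)
class GridSpec:
    """Template grid definition.

    Parameters
    ----------
    west, south, east, north
        Extent in decimal degrees, geographic WGS 84.
    n_rows, n_cols
        Grid shape; must divide the extent exactly by ``cell_size``.
    cell_size
        Cell edge length in degrees (square cells).
    """

    west: float
    south: float
    east: float
    north: float
    n_rows: int
    n_cols: int
    cell_size: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.south < self.north <= 90.0):
            raise GridError(f"latitude extent invalid: [{self.south}, {self.north}]")
        if not (-180.0 <= self.west < self.east <= 180.0):
            raise GridError(f"longitude extent invalid: [{self.west}, {self.east}]")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise GridError("grid shape must be positive")
        if self.cell_size <= 0:
            raise GridError("cell size must be positive")
        tol = _REL_TOL * self.cell_size
        if abs(self.west + self.n_cols * self.cell_size - self.east) > tol:
            raise GridError("extent width is not n_cols * cell_size")
        if abs(self.south + self.n_rows * self.cell_size - self.north) > tol:
            raise GridError("extent height is not n_rows * cell_size")

    @classmethod
    def from_bounds(
        cls, west: float, south: float, east: float, north: float, cell_size: float
    ) -> "GridSpec":
        """Build a grid from an extent and resolution (must divide exactly)."""
        n_cols = int(round((east - west) / cell_size))
        n_rows = int(round((north - south) / cell_size))
        return cls(west, south, east, north, n_rows, n_cols, cell_size)

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def lon_edges(self) -> np.ndarray:
        """Column edge longitudes, west to east, length n_cols + 1."""
        e = self.west + np.arange(self.n_cols + 1) * self.cell_size
        e[-1] = self.east
        return e

    def lat_edges(self) -> np.ndarray:
        """Row edge latitudes, north to south, length n_rows + 1."""
        e = self.north - np.arange(self.n_rows + 1) * self.cell_size
        e[-1] = self.south
        return e

    def cell_bounds(self, r: int, c: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of cell (r, c)."""
        s = self.cell_size
        xmin = self.west + c * s
        ymax = self.north - r * s
        return (xmin, ymax - s, xmin + s, ymax)

    def cell_box(self, r: int, c: int):
        """Shapely box for cell (r, c) (closed box for intersection tests)."""
        return box(*self.cell_bounds(r, c))

    def locate(self, x: float, y: float) -> tuple[int, int]:
        """Row/column of the cell owning point (x, y) under the half-open
        convention; the outer boundary is closed.  Raises
        PointOutsideExtentError for points strictly outside the extent."""
        if not (self.west <= x <= self.east) or not (self.south <= y <= self.north):
            raise PointOutsideExtentError(f"point ({x}, {y}) outside grid extent")
        s = self.cell_size
        c = int(np.floor((x - self.west) / s))
        # snap so the result satisfies the exact edge comparisons
        while c > 0 and x < self.west + c * s:
            c -= 1
        while c < self.n_cols - 1 and x >= self.west + (c + 1) * s:
            c += 1
        c = min(max(c, 0), self.n_cols - 1)
        r = int(np.floor((self.north - y) / s))
        while r > 0 and y > self.north - r * s:
            r -= 1
        while r < self.n_rows - 1 and y <= self.north - (r + 1) * s:
            r += 1
        r = min(max(r, 0), self.n_rows - 1)
        return (r, c)

    def same_as(self, other: "GridSpec") -> bool:
        tol = _REL_TOL * self.cell_size
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.west - other.west) <= tol
            and abs(self.south - other.south) <= tol
            and abs(self.east - other.east) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def require_same(self, other: "GridSpec", what: str = "grids") -> None:
        if not self.same_as(other):
            raise GridAlignmentError(f"{what} are not aligned to the same template")
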