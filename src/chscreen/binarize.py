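"""Presence/absence conversion: precautionary rasterization of vectors,
threshold rules for rasters, and trimming of outsized species ranges.

Rasterization is *precautionary*: a cell is marked present on any
geometric contact with the feature — boundary or corner touch included —
not only when the feature crosses the cell midpoint.  The screening layer
exists to flag places needing further assessment, so over-marking is
preferred to under-marking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .errors import ChscreenError, GeometryError, PointOutsideExtentError, ThresholdError
from .grid import GridSpec
from .preprocess import FractionRaster
from .registry import BinarizeRule, Comparator


@dataclass(frozen=True)
class BinaryLayer:
    """Per-trigger presence/absence grid aligned to the template."""

    shortcode: str
    grid: GridSpec
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.mask.shape != self.grid.shape:
            from .errors import GridAlignmentError

            raise GridAlignmentError(f"layer {self.shortcode} not aligned to grid")


@dataclass(frozen=True)
class TrimReport:
    """Outcome of one range-trimming pass."""

    k: float
    n_total: int
    n_removed: int
    area_removed_fraction: float
    removed_ids: tuple

    def __post_init__(self) -> None:
        if self.n_removed > self.n_total:
            raise ValueError("n_removed exceeds n_total")
        if not (0.0 <= self.area_removed_fraction <= 1.0):
            raise ValueError("area fraction outside [0, 1]")


def _cell_boxes(grid: GridSpec, r0: int, r1: int, c0: int, c1: int):
    """Vectorized shapely boxes for the cell window [r0,r1) x [c0,c1)."""
    s = grid.cell_size
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xmin = grid.west + cols * s
    ymax = grid.north - rows * s
    xx, yy = np.meshgrid(xmin, ymax)
    return shapely.box(xx.ravel(), (yy - s).ravel(), (xx + s).ravel(), yy.ravel())


def rasterize_polygons(
    geom: BaseGeometry, grid: GridSpec, shortcode: str = ""
) -> BinaryLayer:
    """Any-intersection rasterization: cell true iff the geometry
    intersects the closed cell box (corner contact counts)."""
    if not geom.is_valid:
        raise GeometryError("rasterize_polygons requires valid geometry")
    mask = np.zeros(grid.shape, dtype=bool)
    if not geom.is_empty:
        s = grid.cell_size
        parts = getattr(geom, "geoms", [geom])
        for part in parts:
            minx, miny, maxx, maxy = part.bounds
            c0 = max(0, int(np.floor((minx - grid.west) / s)) - 1)
            c1 = min(grid.n_cols, int(np.ceil((maxx - grid.west) / s)) + 1)
            r0 = max(0, int(np.floor((grid.north - maxy) / s)) - 1)
            r1 = min(grid.n_rows, int(np.ceil((grid.north - miny) / s)) + 1)
            if r1 <= r0 or c1 <= c0:
                continue
            boxes = _cell_boxes(grid, r0, r1, c0, c1)
            hit = shapely.intersects(part, boxes).reshape(r1 - r0, c1 - c0)
            mask[r0:r1, c0:c1] |= hit
    return BinaryLayer(shortcode, grid, mask)


def rasterize_midpoint(
    geom: BaseGeometry, grid: GridSpec, shortcode: str = ""
) -> BinaryLayer:
    """Midpoint-rule rasterization (cell true iff its centre is covered).
    Provided as the non-precautionary comparator, not used in the pipeline."""
    s = grid.cell_size
    xs = grid.west + (np.arange(grid.n_cols) + 0.5) * s
    ys = grid.north - (np.arange(grid.n_rows) + 0.5) * s
    xx, yy = np.meshgrid(xs, ys)
    pts = shapely.points(xx.ravel(), yy.ravel())
    mask = shapely.intersects(geom, pts).reshape(grid.shape)
    return BinaryLayer(shortcode, grid, mask)


def rasterize_points(
    points,
    grid: GridSpec,
    shortcode: str = "",
    outside: str = "error",
) -> BinaryLayer:
    """Cell true iff at least one point falls in its half-open box; a point
    on a shared edge belongs to exactly one cell.  Points outside the
    extent raise by default (``outside='drop'`` discards them)."""
    if outside not in ("error", "drop"):
        raise ChscreenError("outside must be 'error' or 'drop'")
    mask = np.zeros(grid.shape, dtype=bool)
    if hasattr(points, "geoms"):
        points = list(points.geoms)
    for p in points:
        if not isinstance(p, Point):
            raise GeometryError("rasterize_points expects point geometries")
        try:
            r, c = grid.locate(p.x, p.y)
        except PointOutsideExtentError:
            if outside == "error":
                raise
            continue
        mask[r, c] = True
    return BinaryLayer(shortcode, grid, mask)


def threshold_raster(
    fr: FractionRaster | np.ndarray,
    rule: BinarizeRule,
    grid: GridSpec | None = None,
    shortcode: str = "",
) -> BinaryLayer:
    """Apply a (comparator, threshold) rule to a [0, 1] raster.

    The comparator is exactly ``ge`` or ``gt`` as configured; the
    distinction matters at threshold-valued cells and is kept first-class
    because a published coverage discrepancy was traced to >=90% vs >90%.
    """
    if isinstance(fr, FractionRaster):
        grid, values = fr.grid, fr.values
    else:
        if grid is None:
            raise ChscreenError("grid required when passing a bare array")
        values = np.asarray(fr)
    if not (0.0 <= rule.threshold <= 1.0):
        raise ThresholdError(f"threshold {rule.threshold} outside [0, 1]")
    if values.size and (values.min() < 0 or values.max() > 1):
        raise ThresholdError("raster values outside [0, 1]")
    if rule.comparator is Comparator.GT:
        mask = values > rule.threshold
    else:
        mask = values >= rule.threshold
    return BinaryLayer(shortcode, grid, mask)


def trim_ranges(
    ranges: list[tuple], k: float
) -> tuple[list[tuple], TrimReport]:
    """Remove ranges whose area exceeds mean + k*SD of *all* input areas.

    Mean and sample (n-1) standard deviation are computed once over the
    full input; the cutoff is strict ``>`` so a degenerate all-equal set
    (SD = 0) removes nothing.  No re-iteration after removal.
    """
    if k <= 0:
        raise ChscreenError("k must be positive")
    if len(ranges) < 2:
        raise ChscreenError("trimming needs at least 2 ranges (SD undefined)")
    areas = np.array([a for _, a, *_ in ranges], dtype=np.float64)
    mean = areas.mean()
    sd = areas.std(ddof=1)
    cutoff = mean + k * sd
    kept = [rec for rec, a in zip(ranges, areas) if not a > cutoff]
    removed = [rec for rec, a in zip(ranges, areas) if a > cutoff]
    total = float(areas.sum())
    removed_area = float(sum(a for _, a, *_ in removed))
    report = TrimReport(
        k=float(k),
        n_total=len(ranges),
        n_removed=len(removed),
        area_removed_fraction=(removed_area / total) if total > 0 else 0.0,
        removed_ids=tuple(rec[0] for rec in removed),
    )
    return kept, report
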