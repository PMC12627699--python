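"""Feature preparation: validity repair, attribute filtering, dissolve,
and aggregation of high-resolution rasters to the template grid.

Vector inputs go through three steps before rasterization: (1) invalid
rings are repaired, (2) records are filtered on their attributes (e.g.
keeping only sites with confirmed status), (3) overlapping polygons and
duplicate points are unioned away so presence is counted once per cell.
High-resolution binary rasters are block-averaged to fractional cover on
the template grid; only exact integer aggregation factors are accepted —
arbitrary regridding is refused rather than silently resampled, because
the aggregation method materially changes feature extent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .errors import (
    GridAlignmentError,
    MixedGeometryError,
    UnrepairableGeometryError,
)
from .grid import GridSpec
from .registry import AttributeFilter


@dataclass(frozen=True)
class FractionRaster:
    """Per-cell fraction of high-resolution presence pixels, in [0, 1]."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise GridAlignmentError("fraction raster not aligned to grid")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("fraction values outside [0, 1]")


def _polygonal(geom: BaseGeometry) -> BaseGeometry:
    """Keep only the polygonal component of a repaired geometry."""
    if geom.geom_type in ("Polygon", "MultiPolygon"):
        return geom
    if geom.geom_type == "GeometryCollection":
        polys = [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
        return shapely.union_all(polys) if polys else shapely.Polygon()
    return geom


def make_valid(geoms: Sequence[BaseGeometry]) -> list[BaseGeometry]:
    """Repair invalid rings; valid inputs pass through untouched.

    Repair uses node-and-rebuild semantics (self-intersections are noded
    and each lobe kept), so a bow-tie quadrilateral becomes a two-triangle
    multipolygon of the same total area.
    """
    out: list[BaseGeometry] = []
    for i, g in enumerate(geoms):
        if g.is_valid:
            out.append(g)
            continue
        try:
            fixed = _polygonal(shapely.make_valid(g))
        except Exception as exc:  # pragma: no cover - GEOS failure path
            raise UnrepairableGeometryError(i, str(exc)) from exc
        if not fixed.is_valid:
            raise UnrepairableGeometryError(i)
        out.append(fixed)
    return out


def filter_features(
    features: Sequence[tuple[BaseGeometry, Mapping]],
    predicate: AttributeFilter | None,
) -> list[tuple[BaseGeometry, Mapping]]:
    """Keep exactly the records whose attributes satisfy the predicate,
    preserving order.  ``predicate=None`` is the identity."""
    if predicate is None:
        return list(features)
    return [(g, a) for g, a in features if predicate.matches(a)]


def dissolve(geoms: Sequence[BaseGeometry]) -> BaseGeometry:
    """Union a collection into one (multi)geometry with no interior
    overlaps; coincident points collapse to one."""
    if not geoms:
        return shapely.GeometryCollection()
    kinds = {
        "point" if isinstance(g, Point) or g.geom_type == "MultiPoint" else "area"
        for g in geoms
    }
    if len(kinds) > 1:
        raise MixedGeometryError("cannot dissolve mixed point/polygon collections")
    return shapely.union_all(list(geoms))


def aggregate_raster(highres: np.ndarray, grid: GridSpec) -> FractionRaster:
    """Block-average a high-resolution binary raster sharing the grid
    extent to per-cell fractional cover (exact arithmetic mean of each
    f x f block)."""
    hr, hc = highres.shape
    if hr % grid.n_rows or hc % grid.n_cols:
        raise GridAlignmentError(
            f"high-res shape {highres.shape} is not an integer multiple of "
            f"grid shape {grid.shape}"
        )
    fr, fc = hr // grid.n_rows, hc // grid.n_cols
    if fr != fc:
        raise GridAlignmentError("row and column aggregation factors differ")
    vals = np.asarray(highres, dtype=np.float64)
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("high-resolution raster must be binary")
    blocks = vals.reshape(grid.n_rows, fr, grid.n_cols, fc)
    return FractionRaster(grid, blocks.sum(axis=(1, 3)) / (fr * fc))
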