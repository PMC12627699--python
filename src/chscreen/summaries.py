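"""Geodesic area accounting, coverage summaries, change analysis and the
two sensitivity sweeps (presence thresholds and range trimming).

All "million km^2"-style reporting rests on per-cell areas computed from
the exact latitude-band formula: on an equiangular grid the area of a cell
depends only on its row.  Two earth models are provided — a sphere with
the authalic radius (default) and the WGS 84 spheroid — because published
screening-layer statistics do not state their area model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binarize import BinaryLayer, BinarizeRule, threshold_raster, trim_ranges
from .combine import ClassGrid, CombinationGrid
from .errors import GridAlignmentError
from .grid import GridSpec
from .preprocess import FractionRaster
from .registry import CHClass

#: authalic (equal-area sphere) Earth radius, km
AUTHALIC_RADIUS_KM = 6371.0072
#: WGS 84 ellipsoid
WGS84_A_KM = 6378.137
WGS84_F = 1.0 / 298.257223563
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)

_CLASS_BY_CODE = {0: CHClass.UNCLASSIFIED, 1: CHClass.POTENTIAL, 10: CHClass.LIKELY}


@dataclass(frozen=True)
class AreaGrid:
    """Per-cell geodesic area (km^2); constant within each latitude band."""

    grid: GridSpec
    cell_area_km2: np.ndarray

    @property
    def total(self) -> float:
        return float(self.cell_area_km2.sum())


class ChangeCategory(str, enum.Enum):
    NEVER = "never"            # 0 -> 0
    NO_CHANGE = "no_change"    # equal nonzero
    ADDED = "added"            # 0 -> {1, 10}
    UPGRADED = "upgraded"      # 1 -> 10
    DOWNGRADED = "downgraded"  # 10 -> 1
    REMOVED = "removed"        # {1, 10} -> 0


#: integer codes used when a change grid is written as a raster
CHANGE_CODES = {
    ChangeCategory.NEVER: 0,
    ChangeCategory.NO_CHANGE: 1,
    ChangeCategory.ADDED: 2,
    ChangeCategory.UPGRADED: 3,
    ChangeCategory.DOWNGRADED: 4,
    ChangeCategory.REMOVED: 5,
}


@dataclass(frozen=True)
class ChangeGrid:
    grid: GridSpec
    category: np.ndarray  # integer CHANGE_CODES values


def _band_sphere(lat_edges_deg: np.ndarray, dlon_deg: float) -> np.ndarray:
    phi = np.radians(lat_edges_deg)
    dlam = np.radians(dlon_deg)
    s = np.sin(phi)
    return AUTHALIC_RADIUS_KM**2 * dlam * (s[:-1] - s[1:])  # edges north->south


def _spheroid_G(phi: np.ndarray) -> np.ndarray:
    # antiderivative of cos(phi) / (1 - e^2 sin^2 phi)^2, halved
    e = np.sqrt(WGS84_E2)
    s = np.sin(phi)
    return 0.5 * (
        s / (1.0 - WGS84_E2 * s**2)
        + np.log((1.0 + e * s) / (1.0 - e * s)) / (2.0 * e)
    )


def _band_spheroid(lat_edges_deg: np.ndarray, dlon_deg: float) -> np.ndarray:
    phi = np.radians(lat_edges_deg)
    dlam = np.radians(dlon_deg)
    G = _spheroid_G(phi)
    return WGS84_A_KM**2 * (1.0 - WGS84_E2) * dlam * (G[:-1] - G[1:])


def cell_areas(grid: GridSpec, model: str = "sphere") -> AreaGrid:
    """Exact per-cell areas from the latitude-band integral."""
    if model not in ("sphere", "spheroid"):
        raise ValueError("model must be 'sphere' or 'spheroid'")
    band = _band_sphere if model == "sphere" else _band_spheroid
    per_row = band(grid.lat_edges(), grid.cell_size)
    return AreaGrid(grid, np.repeat(per_row[:, None], grid.n_cols, axis=1))


# ---------------------------------------------------------------------------
# coverage summaries


def class_coverage(
    class_grid: ClassGrid,
    areas: AreaGrid,
    zones: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per (zone, class) area, % of the zone, and % of the class's total.

    ``zones`` is an optional per-cell label array partitioning the grid
    (e.g. land / EEZ / areas beyond national jurisdiction); omitted, one
    global zone is used.
    """
    class_grid.grid.require_same(areas.grid, "class grid and area grid")
    if zones is None:
        zones = np.zeros(class_grid.grid.shape, dtype=object)
        zones[:] = "global"
    elif zones.shape != class_grid.grid.shape:
        raise GridAlignmentError("zone labels not aligned to grid")
    a = areas.cell_area_km2
    cls = class_grid.values
    class_total = {
        ch: float(a[cls == code].sum()) for code, ch in _CLASS_BY_CODE.items()
    }
    rows = []
    for zone in pd.unique(zones.ravel()):
        zsel = zones == zone
        zarea = float(a[zsel].sum())
        for code, ch in _CLASS_BY_CODE.items():
            carea = float(a[zsel & (cls == code)].sum())
            rows.append(
                {
                    "zone": zone,
                    "ch_class": ch.value,
                    "area_km2": carea,
                    "pct_of_zone": 100.0 * carea / zarea if zarea else 0.0,
                    "pct_within_class": (
                        100.0 * carea / class_total[ch] if class_total[ch] else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)


def criteria_coverage(cg: CombinationGrid, areas: AreaGrid) -> pd.DataFrame:
    """Per (criterion, class) area and % of class area.  Criteria overlap,
    so percentages may sum to more than 100 within a class."""
    cg.grid.require_same(areas.grid, "combination grid and area grid")
    a = areas.cell_area_km2
    value_area: dict[int, float] = {}
    for rec in cg.rat:
        value_area[rec.VALUE] = float(a[cg.values == rec.VALUE].sum())
    class_area = {ch: 0.0 for ch in CHClass}
    for rec in cg.rat:
        class_area[rec.CH] += value_area[rec.VALUE]
    rows = []
    for k in range(1, 6):
        for ch in (CHClass.LIKELY, CHClass.POTENTIAL):
            area = sum(
                value_area[rec.VALUE]
                for rec in cg.rat
                if rec.CH is ch and rec.criterion_flag(k)
            )
            if area == 0.0:
                continue
            rows.append(
                {
                    "criterion": k,
                    "ch_class": ch.value,
                    "area_km2": area,
                    "pct_of_class": (
                        100.0 * area / class_area[ch] if class_area[ch] else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# change analysis


def compare_layers(
    old: ClassGrid, new: ClassGrid, areas: AreaGrid
) -> tuple[ChangeGrid, pd.DataFrame]:
    """Cell-wise change category between two basic layers on one grid,
    plus summed area per category."""
    old.grid.require_same(new.grid, "old and new class grids")
    old.grid.require_same(areas.grid, "class grids and area grid")
    o, n = old.values, new.values
    cat = np.full(o.shape, CHANGE_CODES[ChangeCategory.NEVER], dtype=np.uint8)
    cat[(o == 0) & (n > 0)] = CHANGE_CODES[ChangeCategory.ADDED]
    cat[(o > 0) & (n == 0)] = CHANGE_CODES[ChangeCategory.REMOVED]
    cat[(o == 1) & (n == 10)] = CHANGE_CODES[ChangeCategory.UPGRADED]
    cat[(o == 10) & (n == 1)] = CHANGE_CODES[ChangeCategory.DOWNGRADED]
    cat[(o == n) & (o > 0)] = CHANGE_CODES[ChangeCategory.NO_CHANGE]
    a = areas.cell_area_km2
    rows = [
        {"category": c.value, "area_km2": float(a[cat == code].sum())}
        for c, code in CHANGE_CODES.items()
    ]
    return ChangeGrid(old.grid, cat), pd.DataFrame(rows)


def feature_change_composition(
    change: ChangeGrid, layers: list[BinaryLayer], areas: AreaGrid
) -> pd.DataFrame:
    """Decompose each change category by trigger: area where the trigger is
    present on cells of that category, as absolute km^2, % of the category
    area, and % of the trigger's total area.  Triggers co-occur, so the
    per-category percentages may sum to more than 100."""
    change.grid.require_same(areas.grid, "change grid and area grid")
    a = areas.cell_area_km2
    cat_area = {
        c: float(a[change.category == code].sum()) for c, code in CHANGE_CODES.items()
    }
    rows = []
    for lyr in layers:
        change.grid.require_same(lyr.grid, f"change grid and layer {lyr.shortcode}")
        feat_area = float(a[lyr.mask].sum())
        for c, code in CHANGE_CODES.items():
            both = float(a[lyr.mask & (change.category == code)].sum())
            rows.append(
                {
                    "shortcode": lyr.shortcode,
                    "category": c.value,
                    "area_km2": both,
                    "pct_of_category_area": (
                        100.0 * both / cat_area[c] if cat_area[c] else 0.0
                    ),
                    "pct_of_feature_area": (
                        100.0 * both / feat_area if feat_area else 0.0
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity sweeps


def threshold_sweep(
    fr: FractionRaster,
    thresholds,
    comparator,
    areas: AreaGrid,
) -> pd.DataFrame:
    """Presence area for each candidate threshold (same comparator);
    area is non-increasing as the threshold rises."""
    fr.grid.require_same(areas.grid, "fraction raster and area grid")
    a = areas.cell_area_km2
    rows = []
    for t in thresholds:
        layer = threshold_raster(fr, BinarizeRule(comparator, float(t)))
        area = float(a[layer.mask].sum())
        rows.append(
            {
                "threshold": float(t),
                "area_km2": area,
                "pct_of_grid": 100.0 * area / areas.total,
            }
        )
    return pd.DataFrame(rows)


def trim_sweep(ranges: list[tuple], ks=(3.0, 10.0, 20.0, 50.0)) -> pd.DataFrame:
    """Range-trimming sensitivity: ranges removed and area retained at each
    SD multiplier; the retained-area share is non-decreasing in k."""
    rows = []
    for k in ks:
        _, report = trim_ranges(ranges, k)
        rows.append(
            {
                "k": float(k),
                "n_removed": report.n_removed,
                "pct_area_retained": 100.0 * (1.0 - report.area_removed_fraction),
            }
        )
    return pd.DataFrame(rows)
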