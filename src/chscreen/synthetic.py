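"""Synthetic biodiversity-feature scenes with brute-force ground truth.

The real screening layer is built from licensed global datasets (protected
areas, Key Biodiversity Areas, species ranges, habitat extent rasters...).
This module generates structurally similar inputs — multi-part overlapping
polygons with occasional invalid rings, point records, high-resolution
binary coverage rasters, distribution-model probability rasters, and
heavy-tailed range-area sets — with a known per-cell presence/absence truth,
so every downstream stage is testable without any licensed data.

All generators are pure functions of (parameters, seed).  ``ground_truth``
is a deliberately naive, loop-based oracle sharing no rasterization code
with the pipeline: polygons are tested cell box by cell box with the closed
any-intersection predicate, points by explicit half-open edge comparisons,
rasters by exact integer block sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Point, Polygon, box

from .errors import ChscreenError, GridAlignmentError
from .grid import GridSpec
from .registry import (
    BinarizeRule,
    Comparator,
    GeometryKind,
    Registry,
    TriggerSpec,
)

#: rough km per degree of latitude, used only to scale illustrative
#: range rectangles; the area attribute is the authoritative quantity
_KM_PER_DEG = 111.195


@dataclass(frozen=True)
class CoveragePayload:
    """High-resolution binary coverage raster (e.g. 10–30 m satellite
    classification), ``upscale`` times finer than the template grid."""

    values: np.ndarray  # (n_rows*f, n_cols*f) of {0,1}
    upscale: int


@dataclass(frozen=True)
class SdmPayload:
    """Distribution-model style raster of values in [0, 1] on the grid."""

    values: np.ndarray


@dataclass
class Scene:
    """A synthetic study area: grid, per-trigger payloads, per-trigger truth."""

    grid: GridSpec
    features: list[tuple[TriggerSpec, object]]
    truth: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# generators


def _convex_patch(rng: np.random.Generator, cx: float, cy: float, radius: float) -> Polygon:
    n = int(rng.integers(5, 9))
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = radius * rng.uniform(0.6, 1.4, n)
    xs = cx + rad * np.cos(ang)
    ys = cy + rad * np.sin(ang)
    return Polygon(zip(xs, ys))


def _bowtie_patch(cx: float, cy: float, radius: float) -> Polygon:
    # self-intersecting "bow-tie" ring: exercises validity repair
    r = radius
    return Polygon(
        [(cx - r, cy - r), (cx + r, cy + r), (cx + r, cy - r), (cx - r, cy + r)]
    )


def gen_polygon_feature(
    grid: GridSpec,
    seed: int,
    n_patches: int,
    mean_patch_cells: float = 40.0,
    overlap_fraction: float = 0.3,
    invalid_fraction: float = 0.0,
) -> list[Polygon]:
    """Random polygon patches inside the grid extent.

    ``overlap_fraction`` of the patches are placed so close to an earlier
    patch that they overlap it; ``invalid_fraction`` are emitted as bow-tie
    rings with a self-intersection.  Deterministic given ``seed``.
    """
    if n_patches < 1:
        raise ChscreenError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    radius = np.sqrt(mean_patch_cells * grid.cell_size**2 / np.pi)
    w, h = grid.east - grid.west, grid.north - grid.south
    if 4 * radius > min(w, h):
        raise ChscreenError(
            f"grid extent too small for mean_patch_cells={mean_patch_cells}"
        )
    n_overlap = int(np.floor(overlap_fraction * n_patches))
    n_invalid = int(np.floor(invalid_fraction * n_patches))
    lo_x, hi_x = grid.west + 1.5 * radius, grid.east - 1.5 * radius
    lo_y, hi_y = grid.south + 1.5 * radius, grid.north - 1.5 * radius
    centers: list[tuple[float, float]] = []
    for i in range(n_patches):
        if 1 <= i <= n_overlap and centers:
            # near an existing patch centre so the pair overlaps
            bx, by = centers[0]
            cx = float(np.clip(bx + rng.uniform(-0.5, 0.5) * radius, lo_x, hi_x))
            cy = float(np.clip(by + rng.uniform(-0.5, 0.5) * radius, lo_y, hi_y))
        else:
            cx = float(rng.uniform(lo_x, hi_x))
            cy = float(rng.uniform(lo_y, hi_y))
        centers.append((cx, cy))
    polys: list[Polygon] = []
    for i, (cx, cy) in enumerate(centers):
        if i >= n_patches - n_invalid:
            polys.append(_bowtie_patch(cx, cy, radius))
        else:
            polys.append(_convex_patch(rng, cx, cy, radius))
    return polys


def gen_point_feature(grid: GridSpec, seed: int, n_points: int) -> list[Point]:
    """Uniform random points in the extent; deterministic given seed."""
    if n_points < 0:
        raise ChscreenError("n_points must be >= 0")
    rng = np.random.default_rng(seed)
    xs = rng.uniform(grid.west, grid.east, n_points)
    ys = rng.uniform(grid.south, grid.north, n_points)
    return [Point(x, y) for x, y in zip(xs, ys)]


def gen_coverage_raster(
    grid: GridSpec, seed: int, upscale_factor: int = 4, autocorr_scale: float = 2.0
) -> CoveragePayload:
    """Spatially autocorrelated binary field at ``upscale_factor`` times the
    grid resolution (emulating a 10–30 m presence/absence classification).

    A standard-normal noise field is Gaussian-smoothed with
    ``sigma = autocorr_scale * upscale_factor`` fine pixels (autocorr_scale
    is in template-grid cells) and thresholded at zero.  autocorr_scale -> 0
    recovers an i.i.d. Bernoulli(~0.5) field.
    """
    if upscale_factor < 2:
        raise ChscreenError("upscale_factor must be >= 2")
    rng = np.random.default_rng(seed)
    shape = (grid.n_rows * upscale_factor, grid.n_cols * upscale_factor)
    noise = rng.standard_normal(shape)
    sigma = autocorr_scale * upscale_factor
    field_ = gaussian_filter(noise, sigma=sigma) if sigma > 0 else noise
    return CoveragePayload((field_ > 0).astype(np.uint8), upscale_factor)


def gen_sdm_raster(
    grid: GridSpec, seed: int, autocorr_scale: float = 3.0, steepness: float = 2.0
) -> SdmPayload:
    """Smooth pseudo distribution-model raster with values in [0, 1]:
    a standardized smoothed noise field mapped through a logistic."""
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    f = gaussian_filter(noise, sigma=autocorr_scale) if autocorr_scale > 0 else noise
    z = (f - f.mean()) / (f.std() or 1.0)
    return SdmPayload(1.0 / (1.0 + np.exp(-steepness * z)))


def gen_range_set(
    seed: int,
    n_ranges: int,
    log_area_mu: float = 2.0,
    log_area_sigma: float = 1.0,
    n_outliers: int = 0,
    outlier_multiplier: float = 1000.0,
    extent: tuple[float, float, float, float] = (-180.0, -60.0, 180.0, 60.0),
) -> list[tuple[int, float, Polygon]]:
    """Species-range stand-ins with a heavy-tailed area distribution.

    Areas (km^2) are lognormal; the last ``n_outliers`` of the ``n_ranges``
    are replaced by ``outlier_multiplier`` times the mean of the base draws
    (with +-10% jitter) to emulate exceptionally large ranges of comparable
    magnitude.  Geometries are squares placed in-extent whose side is scaled
    from the area; the ``area_km2`` attribute is the authoritative value.
    """
    if n_ranges < 0:
        raise ChscreenError("n_ranges must be >= 0")
    if n_outliers > n_ranges:
        raise ChscreenError("n_outliers cannot exceed n_ranges")
    rng = np.random.default_rng(seed)
    areas = rng.lognormal(log_area_mu, log_area_sigma, n_ranges)
    if n_outliers:
        base_mean = areas[: n_ranges - n_outliers].mean()
        areas[n_ranges - n_outliers :] = (
            base_mean * outlier_multiplier * rng.uniform(0.9, 1.1, n_outliers)
        )
    west, south, east, north = extent
    out = []
    for i, a in enumerate(areas):
        side = min(np.sqrt(a) / _KM_PER_DEG, (east - west) / 2, (north - south) / 2)
        x0 = rng.uniform(west, east - side)
        y0 = rng.uniform(south, north - side)
        out.append((i, float(a), box(x0, y0, x0 + side, y0 + side)))
    return out


# ---------------------------------------------------------------------------
# scene assembly


_DEFAULT_RULES = {
    "coverage": BinarizeRule(Comparator.GE, 0.5),
    "sdm": BinarizeRule(Comparator.GT, 0.9),
}


def make_scene(
    grid: GridSpec,
    triggers: Sequence[TriggerSpec],
    seed: int,
    n_patches: int = 5,
    mean_patch_cells: float = 40.0,
    overlap_fraction: float = 0.3,
    invalid_fraction: float = 0.2,
    n_points: int = 15,
    upscale_factor: int = 4,
    autocorr_scale: float = 2.0,
) -> Scene:
    """Generate one payload per trigger (by its geometry kind) plus the
    brute-force truth.  Per-trigger seeds are spawned from ``seed`` so each
    feature has an independent stream."""
    children = np.random.SeedSequence(seed).spawn(len(triggers))
    features: list[tuple[TriggerSpec, object]] = []
    for trig, child in zip(triggers, children):
        sub = int(child.generate_state(1)[0] % (2**31))
        if trig.geometry_kind is GeometryKind.POLYGON:
            payload: object = gen_polygon_feature(
                grid, sub, n_patches, mean_patch_cells, overlap_fraction,
                invalid_fraction,
            )
        elif trig.geometry_kind is GeometryKind.POINT:
            payload = gen_point_feature(grid, sub, n_points)
        else:
            rule = trig.binarize_rule or _DEFAULT_RULES["coverage"]
            if rule.threshold > 0.5:  # distribution-model style trigger
                payload = gen_sdm_raster(grid, sub)
            else:
                payload = gen_coverage_raster(grid, sub, upscale_factor, autocorr_scale)
        features.append((trig, payload))
    scene = Scene(grid=grid, features=features, seed=seed)
    scene.truth = ground_truth(scene)
    return scene


# ---------------------------------------------------------------------------
# brute-force oracle


def _truth_polygons(grid: GridSpec, polys: Sequence[Polygon]) -> np.ndarray:
    """Cell true iff a (repaired, unioned) polygon intersects the closed
    cell box.  Plain per-cell loop restricted to the geometry's bbox."""
    mask = np.zeros(grid.shape, dtype=bool)
    geoms = [shapely.make_valid(p) if not p.is_valid else p for p in polys]
    if not geoms:
        return mask
    merged = shapely.union_all(geoms)
    if merged.is_empty:
        return mask
    parts = getattr(merged, "geoms", [merged])
    s = grid.cell_size
    for part in parts:
        minx, miny, maxx, maxy = part.bounds
        c0 = max(0, int(np.floor((minx - grid.west) / s)) - 1)
        c1 = min(grid.n_cols - 1, int(np.ceil((maxx - grid.west) / s)) + 1)
        r0 = max(0, int(np.floor((grid.north - maxy) / s)) - 1)
        r1 = min(grid.n_rows - 1, int(np.ceil((grid.north - miny) / s)) + 1)
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                if not mask[r, c] and part.intersects(grid.cell_box(r, c)):
                    mask[r, c] = True
    return mask


def _truth_points(grid: GridSpec, points: Sequence[Point]) -> np.ndarray:
    """Half-open membership applied as explicit edge comparisons (no floor
    arithmetic shared with the pipeline).  Outer boundary closed."""
    mask = np.zeros(grid.shape, dtype=bool)
    lon = grid.lon_edges()
    lat = grid.lat_edges()
    for p in points:
        x, y = p.x, p.y
        if not (grid.west <= x <= grid.east and grid.south <= y <= grid.north):
            raise ChscreenError(f"point ({x}, {y}) outside extent")
        in_col = (lon[:-1] <= x) & (x < lon[1:])
        if x == grid.east:
            in_col[-1] = True
        in_row = (y <= lat[:-1]) & (lat[1:] < y)
        if y == grid.south:
            in_row[-1] = True
        rows = np.nonzero(in_row)[0]
        cols = np.nonzero(in_col)[0]
        if rows.size and cols.size:
            mask[rows[0], cols[0]] = True
    return mask


def _truth_coverage(grid: GridSpec, payload: CoveragePayload, rule: BinarizeRule) -> np.ndarray:
    f = payload.upscale
    if payload.values.shape != (grid.n_rows * f, grid.n_cols * f):
        raise GridAlignmentError("coverage raster does not align with the grid")
    mask = np.zeros(grid.shape, dtype=bool)
    # exact rational comparison: sum(block) vs threshold * f^2
    thr_num = rule.threshold * f * f
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            s = int(payload.values[r * f : (r + 1) * f, c * f : (c + 1) * f].sum())
            mask[r, c] = s > thr_num if rule.comparator is Comparator.GT else s >= thr_num
    return mask


def _truth_sdm(grid: GridSpec, payload: SdmPayload, rule: BinarizeRule) -> np.ndarray:
    if payload.values.shape != grid.shape:
        raise GridAlignmentError("model raster does not align with the grid")
    mask = np.zeros(grid.shape, dtype=bool)
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            v = payload.values[r, c]
            mask[r, c] = v > rule.threshold if rule.comparator is Comparator.GT else v >= rule.threshold
    return mask


def ground_truth(scene: Scene) -> dict[str, np.ndarray]:
    """Per-trigger boolean presence grids, computed by brute force."""
    out: dict[str, np.ndarray] = {}
    for trig, payload in scene.features:
        if isinstance(payload, CoveragePayload):
            rule = trig.binarize_rule or _DEFAULT_RULES["coverage"]
            out[trig.shortcode] = _truth_coverage(scene.grid, payload, rule)
        elif isinstance(payload, SdmPayload):
            rule = trig.binarize_rule or _DEFAULT_RULES["sdm"]
            out[trig.shortcode] = _truth_sdm(scene.grid, payload, rule)
        elif payload and isinstance(payload[0], Point):
            out[trig.shortcode] = _truth_points(scene.grid, payload)
        else:
            out[trig.shortcode] = _truth_polygons(scene.grid, payload)
    return out


def classify_truth(scene: Scene, registry: Registry) -> np.ndarray:
    """Brute-force hierarchical 0/1/10 class grid from the truth stacks."""
    from .registry import CHClass, classify_feature_set

    codes = {CHClass.UNCLASSIFIED: 0, CHClass.POTENTIAL: 1, CHClass.LIKELY: 10}
    out = np.zeros(scene.grid.shape, dtype=np.uint8)
    shortcodes = [t.shortcode for t, _ in scene.features]
    for r in range(scene.grid.n_rows):
        for c in range(scene.grid.n_cols):
            present = [sc for sc in shortcodes if scene.truth[sc][r, c]]
            ch, _ = classify_feature_set(present, registry)
            out[r, c] = codes[ch]
    return out
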