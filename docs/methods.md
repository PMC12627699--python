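# Methods

This note documents the model behind the package, the conventions and
defaults that matter, what the synthetic scenes do and do not emulate, and
the design choices made where the methodology is genuinely open.

## The screening model

A screening layer is a function from a registry of biodiversity-feature
triggers to a per-cell class on an equiangular WGS 84 grid (default
resolution 30 arcseconds, 1/120°).  Each trigger carries:

* a **shortcode** (`L_*` / `P_*`, the prefix encodes the class),
* a **class**: Likely or Potential Critical Habitat — expert judgement on
  how strongly the dataset evidences IFC PS6 criteria on the ground,
* a **criteria subset** of {1..5} (CR/EN species; endemic/restricted-range
  species; migratory/congregatory concentrations; threatened/unique
  ecosystems; key evolutionary processes),
* a **geometry kind** (polygon, point, raster) and, for rasters, a
  binarization rule (comparator + threshold).

Cell classification is hierarchical and monotone: a cell is Likely if any
present trigger is Likely, else Potential if any trigger is present, else
Unclassified.  Criteria are the union over present triggers.  Adding a
trigger can therefore never demote a cell or shrink its criteria — the
precautionary direction throughout.

The packaged default registry transcribes the published 2025 trigger set:
54 triggers from 22 datasets (31 Likely, 23 Potential).  Two sources in
the published material disagree on the exact trigger list (the RAT
shortcode table lists 52 codes; the feature table lists 55 rows including
a KBA criterion-C row); we reconcile to the stated total of 54 by taking
the 52 RAT shortcodes plus the two KBA A2 rows (`L_KBAA2A`, `P_KBAA2B`)
absent from the RAT table.  Per-trigger criteria assignments follow our
domain reading of the published table (e.g. IBA A1 → criterion 1, IMMA
C1–C3 → criterion 3, forest and ecosystem extent layers → criterion 4,
vents and seeps → criteria 4–5); where a user disagrees, the registry is a
YAML document and every assignment is overrideable.

## Grid conventions

Row 0 is the northernmost row, column 0 the westernmost column.  Cell
(r, c) owns the half-open box `[west + c·s, west + (c+1)·s) ×
(north − (r+1)·s, north − r·s]`: a point on a shared vertical edge belongs
to the eastern cell, on a shared horizontal edge to the northern cell's
southern neighbour (top edge closed).  The outer extent boundary is closed
on all sides so no in-extent point is unassigned.  These conventions are
applied identically in the pipeline (index arithmetic with edge snapping)
and in the ground-truth oracle (explicit edge comparisons), so the two
routes cannot disagree through floating-point drift at exact edges.

## Processing rules

* **Validity repair** uses node-and-rebuild semantics (GEOS `make_valid`,
  keeping the polygonal component): a bow-tie ring becomes a two-lobe
  multipolygon of equal total area.  Valid inputs pass through untouched,
  bit for bit.
* **Dissolve** unions each feature collection so overlapping polygons and
  duplicate points are counted once per cell.  Mixed point/polygon
  collections are refused.
* **Raster aggregation** accepts only exact integer factors and computes
  exact block means; arbitrary regridding is refused rather than silently
  resampled, because the aggregation method materially changes feature
  extent (the package deliberately implements aggregate-then-threshold
  only; the tests demonstrate on striped fixtures that midpoint-style
  resampling flips with stripe phase while block means do not).
* **Precautionary rasterization** marks a cell on any intersection with
  the closed cell box — corner contact counts, and a sliver far from the
  midpoint still marks its cell.  The output is always a superset of the
  midpoint rule (`rasterize_midpoint` exists solely as that comparator).
* **Thresholding** keeps the comparator explicit: defaults are `>= 0.5`
  for fractional-cover triggers and `> 0.9` for distribution-model
  triggers, overrideable per trigger.  At threshold-valued cells `>=` and
  `>` differ exactly there, which is why the distinction is configuration,
  not an implementation detail.
* **Range trimming** removes ranges with area > mean + k·SD, with mean and
  *sample* (n−1) SD computed once over all input areas (no re-iteration
  after removal; population vs sample SD is not specified by the published
  methodology, so the choice is documented here).  The cutoff is strict
  `>` so an all-equal set (SD = 0) removes nothing.

## Combination encoding and products

Presence bitmasks use bit i for the i-th bound trigger in registry order.
Capacity is fixed at 62 layers: flags live in a signed 64-bit integer with
the sign bit and one sentinel excluded.  (The published workflow reports a
limit of ~66 under its own numeric representation; we do not reproduce
that limit, we declare ours and validate it.)  Observed bitmasks get
VALUE ids deterministically — 0 reserved for the all-absent combination,
then 1, 2, ... in ascending bitmask order.  The all-absent combination is
kept in the RAT (class Unclassified) so RAT COUNTs sum to the cell count;
the polygon product drops Unclassified combinations.

Polygonization uses 4-connectivity (corner-touching runs stay separate —
the common raster-polygonize default, and it keeps attributes
unambiguous).  Re-rasterizing the polygon product by the midpoint rule
recovers the non-zero basic cells exactly, since polygons are unions of
cell boxes.

GeoTIFFs are written with plain geographic WGS 84 tags
(ModelPixelScale / ModelTiepoint / GeoKeyDirectory, EPSG:4326) via
tifffile; the RAT sidecar is CSV (always) and dBASE III `.vat.dbf`
(optional); the polygon product is GeoJSON.

## Areas and summaries

Cell areas come from the exact latitude-band integral and depend only on
the row: sphere `A = R²·Δλ·(sin φ_top − sin φ_bot)` with the authalic
radius R = 6371.0072 km (default), or the corresponding WGS 84 ellipsoidal
band integral (`spheroid`).  A global 1° spherical grid sums to 4πR² to
1e−9 relative; the spheroid total reproduces the known 510.066 M km²
surface area.  Class areas (including Unclassified) always partition the
grid total — the conservation property asserted across the suite.

Coverage tables report, per zone and class, area, % of zone and % of the
class's global area; criteria tables report per-criterion areas within a
class, where overlapping criteria legitimately sum past 100%.  Zero-area
criterion rows are omitted (an empty table, not five zero rows, when
nothing is classified).  Zones must partition the grid; resolving
coastal land/EEZ ambiguity is upstream of this package.

Change analysis between two basic layers is cell-wise on identical grids
only (no implicit resampling of mismatched grids — they are refused):
added 0→{1,10}, upgraded 1→10, downgraded 10→1, removed {1,10}→0,
no-change equal nonzero, never 0→0.  Swapping the layers maps
added↔removed and upgraded↔downgraded.

## Synthetic scenes

Generators are pure functions of (parameters, seed); per-trigger seeds are
spawned from the scene seed.  Defaults per 100×100-cell scene: 5 polygon
patches of ~40 cells each with 30% overlapping and 20% invalid (bow-tie)
patches; 15 uniform points; coverage rasters at 4× the grid resolution
with a 2-cell autocorrelation scale (Gaussian-smoothed noise thresholded
at zero, giving ~50% cover); distribution-model rasters as standardized
smooth fields through a logistic.  Range sets draw lognormal(μ=2, σ=1)
areas in km²; planted outliers are set to `outlier_multiplier` times the
mean of the base draws (±10% jitter) rather than scaling their own base
draw, so every planted outlier reliably exceeds the mean + 3·SD cutoff
regardless of which base values were drawn.

The ground-truth oracle shares no rasterization code with the pipeline:
per-cell box-intersection loops for polygons, explicit edge comparisons
for points, exact integer block sums for rasters.  Scenes are small
(0.5–1° extents); the methodology is resolution-agnostic and the grid
object carries the choice.

What synthetic scenes do **not** emulate: real-world spatial distributions
of specific datasets, spherical (great-circle) geometry, the antimeridian,
multi-CRS inputs, and attribute schemas beyond simple status fields.
Passing tests therefore demonstrate the correctness of the processing
rules, not the realism of any global statistic; the published global
figures require the 22 licensed datasets and are out of scope.

## Geometry predicates: planar, not spherical

The published workflow computes on the sphere (S2 great-circle
predicates).  This package uses planar shapely/GEOS predicates, and the
oracle uses the same predicate family, so tests compare like with like.
Whether any cell-boundary intersection verdict at 30 arcseconds ever
differs between planar and spherical predicates is left open here — at
these cell sizes the boxes are nearly planar, but no bound is claimed.
Inputs must be geographic WGS 84; projected inputs are rejected rather
than reprojected.

## Numerical choices

* Grid divisibility and alignment checks use 1e−9 relative tolerance on
  the cell size; area conservation is asserted at 1e−9 relative;
  dissolve idempotence at 1e−9 relative area.
* Aggregation means are exact block sums divided once; mass conservation
  holds to 1e−12.
* Point-in-cell assignment snaps floor-based indices to the exact edge
  comparisons, so edge-sitting points land deterministically.
* Percentages are printed to 2 decimals in CLI output; underlying values
  keep full precision in CSVs.

## Problem sizes

The test suite and the acceptance script run 20 mixed scenes of 100×100
cells (five triggers each: two polygon, one point, one coverage-raster,
one model-raster) for oracle equivalence, 10-seed batches for the
monotonicity and change-analysis properties, and a 360×180 one-degree
global grid for the area checks.  These sizes exercise every code path —
multi-part geometries, edge-sitting points, threshold ties, planted
outliers — while keeping a full run in seconds.

## Known limitations

* No spherical predicates; no antimeridian handling (extents are split at
  the boundary by construction).
* No reprojection; no tiling/pyramids — single desk-scale grids.
* Per-source raster preprocessing beyond aggregate-and-threshold is
  configuration for the user, not built in.
* The registry's criteria assignments are our documented transcription of
  an ambiguous published table; users with access to the supplementary
  material can override any entry in YAML.
* Partial-cell area weighting is deliberately absent: presence is binary
  by design in a precautionary screening product.
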