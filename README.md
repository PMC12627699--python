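# chscreen

A pipeline for building and analysing **Critical Habitat screening layers**
on a global latitude/longitude grid.

The International Finance Corporation's Performance Standard 6 (IFC PS6)
defines Critical Habitat as areas of high biodiversity value, assessed
against five criteria: (1) Critically Endangered or Endangered species,
(2) endemic and/or restricted-range species, (3) globally significant
concentrations of migratory or congregatory species, (4) highly threatened
and/or unique ecosystems, and (5) key evolutionary processes.  A *screening
layer* classifies every grid cell as **Likely**, **Potential** or
**Unclassified** Critical Habitat from a registry of biodiversity-feature
*triggers* — (dataset, designation-criterion) pairs such as "Important Bird
and Biodiversity Areas under criterion A1" — each mapped by expert judgement
to a class and a subset of the five criteria.  The result is a desk-screening
aid for directing impact avoidance and full on-the-ground assessment, not a
determination of actual Critical Habitat.

The package is aimed at conservation analysts who need to rebuild, update
or audit such a layer: the trigger registry is configuration, every
processing rule is explicit and tested, and all downstream statistics are
reproducible from a config file and a seed.

## What it computes

For each trigger the pipeline prepares the input (validity repair,
attribute filtering, union/dissolve for vectors; exact block-mean
aggregation to fractional cover for high-resolution rasters) and converts
it to a presence/absence grid:

* **vector features** are rasterized *precautionarily*: a cell is present
  on **any** geometric contact with the feature, not only when the feature
  crosses the cell midpoint; point features mark the single cell whose
  half-open box contains them;
* **raster features** are thresholded with an explicit comparator —
  fractional-cover layers with `>= 0.5`, distribution-model layers with
  `> 0.9` by default.  The `>=`/`>` distinction is first-class because it
  visibly changes feature extent at threshold-valued cells.

The binary layers are combined so that each cell's unique combination of
triggers gets a unique integer (bit flags over registry order, up to 62
triggers), and the hierarchy Likely > Potential > Unclassified gives the
cell class.  Three products are written:

1. **basic raster** — 8-bit GeoTIFF with values 0 / 1 / 10
   (Unclassified / Potential / Likely);
2. **drill-down raster + RAT** — integer GeoTIFF of combination ids plus a
   raster attribute table (`.vat.csv`, optionally `.vat.dbf`) with columns
   VALUE, COUNT, CH, C1..C5 and one presence flag per trigger;
3. **drill-down polygons** — 4-connected runs of same-combination cells
   dissolved to polygons with decoded attributes (GeoJSON), Unclassified
   combinations excluded.

On top sit analysis operations: exact latitude-band cell areas (authalic
sphere or WGS 84 spheroid), coverage by class/criterion/zone, change
analysis against a previous layer (added / upgraded / no change /
downgraded / removed), per-trigger change decomposition, a
presence-threshold sweep and a species-range trimming sweep (removing
ranges larger than mean + k·SD of all range areas).

Real global inputs (protected areas, Key Biodiversity Areas, IUCN Red List
ranges, habitat extent rasters, ...) are licensed and are not bundled.  The
`synthetic` module generates structurally faithful stand-ins — overlapping
and invalid polygons, point records, autocorrelated high-resolution
coverage rasters, probability rasters, heavy-tailed range-area sets — with
a brute-force per-cell ground truth, so every stage is verified
cell-for-cell against an independent oracle.

## Worked example

```python
import chscreen as ch

grid = ch.GridSpec.from_bounds(0.0, 0.0, 0.5, 0.5, ch.CELL_30_ARCSEC)   # 60x60 cells
registry = ch.load_registry().subset(
    ["L_COLDSEEP", "P_COLDREEF", "L_IBAA1", "P_SEAMOUNT", "L_MOISTFOR"]
)
scene = ch.make_scene(grid, list(registry), seed=11)

from chscreen.cli import build_binary_layers
layers = build_binary_layers(grid, scene.features, registry)
cg = ch.encode_combinations(layers, registry)
basic = ch.to_basic(cg)

areas = ch.cell_areas(grid)
coverage = ch.class_coverage(basic, areas)
print(coverage.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"{len(cg.rat)} unique feature combinations, "
      f"{len(ch.polygonize(cg))} drill-down polygons")
```

prints

```
  zone     ch_class  area_km2  pct_of_zone  pct_within_class
global Unclassified   1085.30        35.11            100.00
global    Potential    341.73        11.06            100.00
global       Likely   1664.01        53.83            100.00
19 unique feature combinations, 100 drill-down polygons
```

Reading: on this half-degree synthetic scene with five triggers (points,
polygons, a distribution-model raster and a coverage raster), 53.83% of
the area carries at least one Likely trigger, a further 11.06% only
Potential triggers, and the rest intersects no trigger.  The 19 RAT rows
are the distinct trigger combinations observed; the 100 polygons are their
connected runs, Unclassified excluded.

The same pipeline is available from the shell, driven by a YAML config:

```bash
chscreen generate   --config config.yaml   # seeded synthetic scene
chscreen build      --config config.yaml   # the three products + manifest
chscreen summarize  --config config.yaml   # coverage tables (CSV)
chscreen compare    --config config.yaml   # change analysis vs previous layer
chscreen sensitivity --config config.yaml  # threshold + trimming sweeps
```

Every run writes a `manifest.json` (config hash, seed, versions, output
hashes); rebuilding with the same config is bit-identical.

## Layout

```
src/chscreen/
  registry.py    trigger registry (packaged default: data/default_registry.yaml)
  grid.py        template GridSpec and cell-ownership conventions
  synthetic.py   scene generators + brute-force ground-truth oracle
  preprocess.py  make_valid / filter / dissolve / aggregate_raster
  binarize.py    precautionary rasterization, thresholds, range trimming
  combine.py     combination encoding, RAT, basic 0/1/10 grid
  products.py    GeoTIFF / RAT sidecar / polygon product I/O
  summaries.py   areas, coverage, change analysis, sensitivity sweeps
  cli.py         config-driven orchestration (generate/build/summarize/...)
docs/methods.md  model, conventions, parameter defaults, limitations
```
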