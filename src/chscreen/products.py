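"""Read/write the three published product formats.

1. Basic raster: single-band 8-bit GeoTIFF, values {0, 1, 10}.
2. Drill-down raster: integer GeoTIFF of combination VALUE ids plus a
   raster attribute table sidecar (`<raster>.vat.csv` always; a dBASE
   `<raster>.vat.dbf` optionally, matching the GIS VAT convention).
3. Drill-down polygons: 4-connected runs of cells sharing a VALUE,
   dissolved into polygons with the decoded attributes; Unclassified
   combinations are excluded.  Written as GeoJSON.

GeoTIFFs carry plain geographic WGS 84 georeferencing via the standard
ModelPixelScale / ModelTiepoint / GeoKeyDirectory tags.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import json

import numpy as np
import pandas as pd
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import box, mapping

from .combine import ClassGrid, CombinationGrid, RATRecord
from .errors import ProductValueError, RatConsistencyError
from .grid import GridSpec
from .registry import CHClass

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735

# GeoKeyDirectory: geographic model, pixel-is-area, EPSG:4326
_GEO_KEYS = (
    1, 1, 0, 3,
    1024, 0, 1, 2,
    1025, 0, 1, 1,
    2048, 0, 1, 4326,
)

#: 4-connectivity structuring element for polygonization
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _geo_extratags(grid: GridSpec):
    s = grid.cell_size
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.west, grid.north, 0.0)),
        (_TAG_GEO_KEYS, "H", len(_GEO_KEYS), _GEO_KEYS),
    ]


def write_geotiff(array: np.ndarray, grid: GridSpec, path: str | Path) -> None:
    """Write a single-band georeferenced TIFF aligned to the grid."""
    if array.shape != grid.shape:
        raise ProductValueError("array shape does not match grid")
    tifffile.imwrite(
        str(path),
        array,
        photometric="minisblack",
        extratags=_geo_extratags(grid),
    )


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read a single-band georeferenced TIFF back to (array, GridSpec)."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        array = page.asarray()
        scale = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
    sx, sy = float(scale[0]), float(scale[1])
    if abs(sx - sy) > 1e-12 * sx:
        raise ProductValueError("non-square cells in georeferencing")
    west, north = float(tie[3]), float(tie[4])
    n_rows, n_cols = array.shape
    grid = GridSpec(
        west=west,
        south=north - n_rows * sy,
        east=west + n_cols * sx,
        north=north,
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=sx,
    )
    return array, grid


# ---------------------------------------------------------------------------
# basic product


def write_basic(class_grid: ClassGrid, path: str | Path) -> None:
    """Basic layer: uint8 GeoTIFF with values {0, 1, 10}, no nodata."""
    vals = class_grid.values
    bad = set(np.unique(vals)) - {0, 1, 10}
    if bad:
        raise ProductValueError(f"basic layer values outside {{0,1,10}}: {sorted(bad)}")
    write_geotiff(vals.astype(np.uint8), class_grid.grid, path)


def read_basic(path: str | Path) -> ClassGrid:
    array, grid = read_geotiff(path)
    return ClassGrid(grid, array)


# ---------------------------------------------------------------------------
# drill-down raster + RAT sidecar


def rat_to_frame(cg: CombinationGrid) -> pd.DataFrame:
    """RAT as a table with the published column layout: VALUE, COUNT, CH,
    C1..C5, then one 0/1 column per registry shortcode (registry order)."""
    rows = []
    for rec in cg.rat:
        row: dict = {
            "VALUE": rec.VALUE,
            "COUNT": rec.COUNT,
            "CH": rec.CH.value,
        }
        for k in range(1, 6):
            row[f"C{k}"] = int(rec.criterion_flag(k))
        for code in cg.registry.shortcodes:
            row[code] = int(code in rec.shortcodes)
        rows.append(row)
    return pd.DataFrame(rows).sort_values("VALUE").reset_index(drop=True)


def write_drilldown(
    cg: CombinationGrid, path: str | Path, dbf: bool = False
) -> None:
    """Write the VALUE raster plus its `.vat.csv` sidecar (and optionally a
    dBASE `.vat.dbf`)."""
    path = Path(path)
    in_grid = set(np.unique(cg.values))
    in_rat = {rec.VALUE for rec in cg.rat}
    if not in_grid <= in_rat:
        raise RatConsistencyError(
            f"grid values missing from RAT: {sorted(in_grid - in_rat)}"
        )
    write_geotiff(cg.values.astype(np.int32), cg.grid, path)
    frame = rat_to_frame(cg)
    frame.to_csv(path.with_name(path.name + ".vat.csv"), index=False)
    if dbf:
        _write_dbf(frame, path.with_name(path.name + ".vat.dbf"))


def read_drilldown(path: str | Path) -> tuple[np.ndarray, GridSpec, pd.DataFrame]:
    path = Path(path)
    array, grid = read_geotiff(path)
    frame = pd.read_csv(path.with_name(path.name + ".vat.csv"))
    return array, grid, frame


def _write_dbf(frame: pd.DataFrame, path: Path) -> None:
    """Minimal dBASE III writer for the VAT sidecar (numeric, character and
    logical fields only)."""
    fields = []  # (name, type, length)
    for col in frame.columns:
        if col in ("VALUE", "COUNT"):
            fields.append((col, b"N", 10))
        elif col == "CH":
            fields.append((col, b"C", 12))
        else:
            fields.append((col, b"L", 1))
    record_size = 1 + sum(length for _, _, length in fields)
    header_size = 32 + 32 * len(fields) + 1
    with open(path, "wb") as fh:
        fh.write(struct.pack("<B3BLHH20x", 0x03, 26, 1, 1, len(frame),
                             header_size, record_size))
        for name, ftype, length in fields:
            fh.write(struct.pack("<11s1s4xBB14x", name.encode()[:10], ftype,
                                 length, 0))
        fh.write(b"\x0d")
        for _, row in frame.iterrows():
            fh.write(b" ")
            for name, ftype, length in fields:
                v = row[name]
                if ftype == b"N":
                    fh.write(str(int(v)).rjust(length).encode())
                elif ftype == b"C":
                    fh.write(str(v).ljust(length)[:length].encode())
                else:
                    fh.write(b"T" if int(v) else b"F")
        fh.write(b"\x1a")


# ---------------------------------------------------------------------------
# polygon product


@dataclass(frozen=True)
class DrillDownPolygon:
    """One dissolved run of same-combination cells with decoded attributes."""

    geometry: shapely.geometry.base.BaseGeometry
    CH: CHClass
    CRITERIA: tuple[int, ...]
    ALL_FEATURES: tuple[str, ...]
    by_criterion: dict[int, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.CH is CHClass.UNCLASSIFIED:
            raise ProductValueError("Unclassified polygons are excluded")
        if not self.ALL_FEATURES:
            raise ProductValueError("polygon without features")


def polygonize(cg: CombinationGrid) -> list[DrillDownPolygon]:
    """Dissolve maximal 4-connected runs of cells sharing a VALUE into one
    polygon each, dropping Unclassified combinations."""
    out: list[DrillDownPolygon] = []
    grid = cg.grid
    for rec in cg.rat:
        if rec.CH is CHClass.UNCLASSIFIED:
            continue
        sel = cg.values == rec.VALUE
        labels, n = ndimage.label(sel, structure=_FOUR_CONN)
        crit = tuple(sorted(rec.criteria))
        feats = tuple(sorted(rec.shortcodes))
        by_crit = {
            k: tuple(
                sorted(
                    c for c in rec.shortcodes
                    if k in cg.registry.get(c).criteria
                )
            )
            for k in range(1, 6)
        }
        for lab in range(1, n + 1):
            rows, cols = np.nonzero(labels == lab)
            boxes = [grid.cell_box(r, c) for r, c in zip(rows, cols)]
            geom = shapely.union_all(boxes)
            out.append(
                DrillDownPolygon(
                    geometry=geom,
                    CH=rec.CH,
                    CRITERIA=crit,
                    ALL_FEATURES=feats,
                    by_criterion=by_crit,
                )
            )
    return out


def write_polygons(polys: list[DrillDownPolygon], path: str | Path) -> None:
    """Write the polygon product as GeoJSON; list attributes are serialized
    as semicolon-joined sorted values."""
    features = []
    for p in polys:
        props = {
            "CH": p.CH.value,
            "CRITERIA": ";".join(str(k) for k in p.CRITERIA),
            "ALL_FEATURES": ";".join(p.ALL_FEATURES),
        }
        for k in range(1, 6):
            props[f"C{k}"] = ";".join(p.by_criterion.get(k, ()))
        features.append(
            {"type": "Feature", "geometry": mapping(p.geometry), "properties": props}
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc))


def read_polygons(path: str | Path) -> list[DrillDownPolygon]:
    doc = json.loads(Path(path).read_text())
    out = []
    for feat in doc["features"]:
        props = feat["properties"]
        out.append(
            DrillDownPolygon(
                geometry=shapely.geometry.shape(feat["geometry"]),
                CH=CHClass(props["CH"]),
                CRITERIA=tuple(int(k) for k in props["CRITERIA"].split(";") if k),
                ALL_FEATURES=tuple(c for c in props["ALL_FEATURES"].split(";") if c),
                by_criterion={
                    k: tuple(c for c in props[f"C{k}"].split(";") if c)
                    for k in range(1, 6)
                },
            )
        )
    return out
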