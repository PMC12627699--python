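"""Combine binary trigger layers into the drill-down combination grid with
its raster attribute table (RAT), and derive the basic 0/1/10 class grid.

Each cell's set of present triggers is encoded as a bitmask (bit i = layer
i present, layer order following registry order); every *observed* bitmask
gets a VALUE id — 0 for the all-absent combination, then 1, 2, ... in
ascending bitmask order.  The RAT decodes VALUE back to per-trigger flags,
the hierarchical class (Likely > Potential > Unclassified), and the IFC
PS6 criteria triggered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binarize import BinaryLayer
from .errors import (
    CapacityExceededError,
    ChscreenError,
    GridAlignmentError,
    RatConsistencyError,
)
from .grid import GridSpec
from .registry import CHClass, Registry, classify_feature_set

#: basic-layer cell values
CLASS_CODES = {CHClass.UNCLASSIFIED: 0, CHClass.POTENTIAL: 1, CHClass.LIKELY: 10}


@dataclass(frozen=True)
class RATRecord:
    """One raster-attribute-table row: a unique observed feature combination."""

    VALUE: int
    COUNT: int
    CH: CHClass
    criteria: frozenset[int]
    shortcodes: frozenset[str]  # triggers present in this combination

    def criterion_flag(self, k: int) -> bool:
        return k in self.criteria


@dataclass(frozen=True)
class CombinationGrid:
    """Drill-down product: per-cell VALUE ids plus the decoding RAT."""

    grid: GridSpec
    values: np.ndarray
    rat: tuple[RATRecord, ...]
    registry: Registry

    def record(self, value_id: int) -> RATRecord:
        for rec in self.rat:
            if rec.VALUE == value_id:
                return rec
        raise RatConsistencyError(f"VALUE {value_id} not in raster attribute table")


@dataclass(frozen=True)
class ClassGrid:
    """Basic product: per-cell 0 (Unclassified) / 1 (Potential) / 10 (Likely)."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.shape:
            raise GridAlignmentError("class grid not aligned to template")
        bad = set(np.unique(self.values)) - {0, 1, 10}
        if bad:
            from .errors import ProductValueError

            raise ProductValueError(f"class grid contains invalid values {sorted(bad)}")


def encode_combinations(
    layers: list[BinaryLayer], registry: Registry
) -> CombinationGrid:
    """Stack binary layers into the unique-combination grid.

    Layers must share one template grid and appear in registry order (their
    order defines bit positions).  At most ``registry.capacity`` layers are
    supported by the signed-64-bit flag encoding.
    """
    if not layers:
        raise ChscreenError("at least one layer required")
    if len(layers) > registry.capacity:
        raise CapacityExceededError(
            f"{len(layers)} layers exceed the combination-encoding capacity "
            f"of {registry.capacity} triggers this workflow supports"
        )
    grid = layers[0].grid
    indices = []
    for lyr in layers:
        grid.require_same(lyr.grid, f"layer {lyr.shortcode} and template")
        indices.append(registry.index(lyr.shortcode))
    if indices != sorted(indices):
        raise ChscreenError("layers must be supplied in registry order")
    if len(set(indices)) != len(indices):
        raise ChscreenError("duplicate layers for one shortcode")

    bitmask = np.zeros(grid.shape, dtype=np.uint64)
    for i, lyr in enumerate(layers):
        bitmask |= lyr.mask.astype(np.uint64) << np.uint64(i)

    observed, inverse, counts = np.unique(
        bitmask, return_inverse=True, return_counts=True
    )
    # VALUE ids: 0 reserved for the all-absent combination; non-empty
    # combinations numbered 1.. in ascending bitmask order.
    has_empty = observed[0] == 0
    value_ids = np.arange(1 - int(has_empty), len(observed) + 1 - int(has_empty))
    if has_empty:
        value_ids[0] = 0
    values = value_ids[inverse].reshape(grid.shape).astype(np.int64)

    records = []
    for vid, bits, count in zip(value_ids, observed, counts):
        present = frozenset(
            lyr.shortcode
            for i, lyr in enumerate(layers)
            if (int(bits) >> i) & 1
        )
        ch, crit = classify_feature_set(present, registry)
        records.append(
            RATRecord(
                VALUE=int(vid),
                COUNT=int(count),
                CH=ch,
                criteria=crit,
                shortcodes=present,
            )
        )
    return CombinationGrid(grid=grid, values=values, rat=tuple(records), registry=registry)


def decode(value_id: int, rat: tuple[RATRecord, ...] | CombinationGrid) -> frozenset[str]:
    """Set of trigger shortcodes for a VALUE id (inverse of the encoding)."""
    records = rat.rat if isinstance(rat, CombinationGrid) else rat
    for rec in records:
        if rec.VALUE == value_id:
            return rec.shortcodes
    raise RatConsistencyError(f"VALUE {value_id} not in raster attribute table")


def to_basic(cg: CombinationGrid) -> ClassGrid:
    """Map each cell's combination to the basic 0/1/10 class value."""
    lut = np.zeros(int(cg.values.max()) + 1, dtype=np.uint8)
    for rec in cg.rat:
        lut[rec.VALUE] = CLASS_CODES[rec.CH]
    return ClassGrid(cg.grid, lut[cg.values])
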