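"""Trigger registry: biodiversity features, their Critical Habitat class and
IFC PS6 criteria.

A *trigger* is one (dataset, designation-criterion) pair — e.g. "Important
Bird and Biodiversity Areas under criterion A1" — mapped by expert judgement
to a screening class (Likely or Potential Critical Habitat) and to the
subset of the five IFC Performance Standard 6 criteria it evidences:

1. Critically Endangered or Endangered species
2. Endemic and/or restricted-range species
3. Globally significant concentrations of migratory/congregatory species
4. Highly threatened and/or unique ecosystems
5. Key evolutionary processes

The packaged default registry (``data/default_registry.yaml``) transcribes
the published trigger set: 54 triggers drawn from 22 global datasets.
Registry order is significant — it fixes the bit positions of the
combination encoding downstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import (
    CapacityExceededError,
    ClassPrefixMismatchError,
    DuplicateShortcodeError,
    EmptyCriteriaError,
    InvalidCriteriaError,
    MissingBinarizeRuleError,
    RegistryError,
    UnknownShortcodeError,
)

#: Bit-flag combinations are held in a signed 64-bit integer; the sign bit and
#: one sentinel value are excluded, leaving room for 62 trigger layers.
DEFAULT_CAPACITY = 62

VALID_CRITERIA = frozenset({1, 2, 3, 4, 5})


class CHClass(str, enum.Enum):
    """Screening class of a cell or trigger."""

    LIKELY = "Likely"
    POTENTIAL = "Potential"
    UNCLASSIFIED = "Unclassified"


class GeometryKind(str, enum.Enum):
    POLYGON = "polygon"
    POINT = "point"
    RASTER = "raster"


class Comparator(str, enum.Enum):
    """Binarization comparator.  The ge/gt distinction is first-class: a
    published octocoral discrepancy traces to >=90% vs >90% thresholds."""

    GT = "gt"
    GE = "ge"


@dataclass(frozen=True)
class BinarizeRule:
    comparator: Comparator
    threshold: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.threshold <= 1.0):
            raise MissingBinarizeRuleError(
                f"binarize threshold {self.threshold} outside [0, 1]"
            )


@dataclass(frozen=True)
class AttributeFilter:
    """Equality/membership predicate on a named feature attribute."""

    attribute: str
    values: tuple

    def matches(self, record: Mapping) -> bool:
        from .errors import MissingAttributeError

        if self.attribute not in record:
            raise MissingAttributeError(
                f"filter references missing attribute {self.attribute!r}"
            )
        return record[self.attribute] in self.values


@dataclass(frozen=True)
class TriggerSpec:
    """One biodiversity-feature trigger."""

    shortcode: str
    dataset: str
    description: str
    ch_class: CHClass
    criteria: frozenset[int]
    geometry_kind: GeometryKind
    filter: AttributeFilter | None = None
    binarize_rule: BinarizeRule | None = None

    def __post_init__(self) -> None:
        prefix = self.shortcode.split("_", 1)[0]
        if prefix not in ("L", "P"):
            raise ClassPrefixMismatchError(
                f"{self.shortcode}: shortcode must start with L_ or P_"
            )
        expected = CHClass.LIKELY if prefix == "L" else CHClass.POTENTIAL
        if self.ch_class is not expected:
            raise ClassPrefixMismatchError(
                f"{self.shortcode}: prefix implies {expected.value}, "
                f"declared {self.ch_class.value}"
            )
        if not self.criteria:
            raise EmptyCriteriaError(f"{self.shortcode}: criteria set is empty")
        if not set(self.criteria) <= VALID_CRITERIA:
            raise InvalidCriteriaError(
                f"{self.shortcode}: criteria {sorted(self.criteria)} not in 1..5"
            )
        if (self.geometry_kind is GeometryKind.RASTER) != (
            self.binarize_rule is not None
        ):
            raise MissingBinarizeRuleError(
                f"{self.shortcode}: binarize rule required iff geometry kind is raster"
            )


@dataclass(frozen=True)
class Registry:
    """Ordered, validated collection of triggers."""

    triggers: tuple[TriggerSpec, ...]
    capacity: int = DEFAULT_CAPACITY

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise RegistryError("capacity must be positive")
        seen: set[str] = set()
        for t in self.triggers:
            if t.shortcode in seen:
                raise DuplicateShortcodeError(f"duplicate shortcode {t.shortcode}")
            seen.add(t.shortcode)
        if len(self.triggers) > self.capacity:
            raise CapacityExceededError(
                f"{len(self.triggers)} triggers exceed combination-encoding "
                f"capacity {self.capacity}"
            )

    def __len__(self) -> int:
        return len(self.triggers)

    def __iter__(self):
        return iter(self.triggers)

    @property
    def shortcodes(self) -> tuple[str, ...]:
        return tuple(t.shortcode for t in self.triggers)

    def get(self, shortcode: str) -> TriggerSpec:
        for t in self.triggers:
            if t.shortcode == shortcode:
                return t
        raise UnknownShortcodeError(f"unknown shortcode {shortcode}")

    def index(self, shortcode: str) -> int:
        for i, t in enumerate(self.triggers):
            if t.shortcode == shortcode:
                return i
        raise UnknownShortcodeError(f"unknown shortcode {shortcode}")

    @property
    def datasets(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.triggers:
            seen.setdefault(t.dataset)
        return tuple(seen)

    def subset(self, shortcodes: Sequence[str]) -> "Registry":
        """Registry restricted to the given shortcodes, registry order kept."""
        want = set(shortcodes)
        missing = want - set(self.shortcodes)
        if missing:
            raise UnknownShortcodeError(f"unknown shortcodes {sorted(missing)}")
        return Registry(
            tuple(t for t in self.triggers if t.shortcode in want), self.capacity
        )


def _parse_trigger(entry: Mapping) -> TriggerSpec:
    flt = None
    if entry.get("filter") is not None:
        f = entry["filter"]
        flt = AttributeFilter(attribute=f["attribute"], values=tuple(f["values"]))
    rule = None
    if entry.get("binarize") is not None:
        b = entry["binarize"]
        rule = BinarizeRule(Comparator(b["comparator"]), float(b["threshold"]))
    return TriggerSpec(
        shortcode=entry["shortcode"],
        dataset=entry["dataset"],
        description=entry.get("description", ""),
        ch_class=CHClass(entry["ch_class"]),
        criteria=frozenset(int(c) for c in entry["criteria"]),
        geometry_kind=GeometryKind(entry["geometry_kind"]),
        filter=flt,
        binarize_rule=rule,
    )


def load_registry(source: str | Path | Mapping | None = None) -> Registry:
    """Load and validate a trigger registry.

    ``source`` may be a path to a YAML document, an already-parsed mapping,
    or None for the packaged default registry.  Document order is preserved
    (it defines combination bit positions).
    """
    if source is None:
        with resources.files("chscreen.data").joinpath(
            "default_registry.yaml"
        ).open() as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    if not isinstance(doc, Mapping) or "triggers" not in doc:
        raise RegistryError("registry document must be a mapping with 'triggers'")
    capacity = int(doc.get("capacity", DEFAULT_CAPACITY))
    triggers = tuple(_parse_trigger(e) for e in doc["triggers"])
    return Registry(triggers, capacity)


def dump_registry(registry: Registry) -> dict:
    """Serialize a registry back to its document form (lossless round-trip)."""
    out = []
    for t in registry:
        entry: dict = {
            "shortcode": t.shortcode,
            "dataset": t.dataset,
            "description": t.description,
            "ch_class": t.ch_class.value,
            "criteria": sorted(t.criteria),
            "geometry_kind": t.geometry_kind.value,
        }
        if t.filter is not None:
            entry["filter"] = {
                "attribute": t.filter.attribute,
                "values": list(t.filter.values),
            }
        if t.binarize_rule is not None:
            entry["binarize"] = {
                "comparator": t.binarize_rule.comparator.value,
                "threshold": t.binarize_rule.threshold,
            }
        out.append(entry)
    return {"capacity": registry.capacity, "triggers": out}


def classify_feature_set(
    present: Iterable[str], registry: Registry
) -> tuple[CHClass, frozenset[int]]:
    """Hierarchical classification of a cell from its present triggers.

    Likely > Potential > Unclassified: a single Likely trigger makes the
    cell Likely, otherwise any Potential trigger makes it Potential.  The
    criteria are the union over present triggers (empty iff Unclassified).
    """
    ch = CHClass.UNCLASSIFIED
    criteria: set[int] = set()
    for code in set(present):
        t = registry.get(code)  # raises UnknownShortcodeError
        criteria |= t.criteria
        if t.ch_class is CHClass.LIKELY:
            ch = CHClass.LIKELY
        elif ch is CHClass.UNCLASSIFIED:
            ch = CHClass.POTENTIAL
    return ch, frozenset(criteria)
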