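import numpy as np
import pytest

from chscreen import GridSpec, load_registry
from chscreen.registry import (
    BinarizeRule,
    CHClass,
    Comparator,
    GeometryKind,
    Registry,
    TriggerSpec,
)


def make_trigger(
    shortcode,
    criteria=(1,),
    kind="polygon",
    dataset=None,
    comparator="ge",
    threshold=0.5,
    flt=None,
):
    """Compact TriggerSpec builder for tests; class inferred from prefix."""
    ch = CHClass.LIKELY if shortcode.startswith("L_") else CHClass.POTENTIAL
    rule = (
        BinarizeRule(Comparator(comparator), threshold) if kind == "raster" else None
    )
    return TriggerSpec(
        shortcode=shortcode,
        dataset=dataset or shortcode,
        description="",
        ch_class=ch,
        criteria=frozenset(criteria),
        geometry_kind=GeometryKind(kind),
        filter=flt,
        binarize_rule=rule,
    )


@pytest.fixture(scope="session")
def default_registry():
    return load_registry()


@pytest.fixture
def toy_registry():
    """Three triggers: one Likely polygon, one Potential polygon, one
    Potential raster."""
    return Registry(
        (
            make_trigger("L_A", criteria=(1, 4)),
            make_trigger("P_B", criteria=(3,)),
            make_trigger("P_C", criteria=(4,), kind="raster"),
        )
    )


@pytest.fixture
def small_grid():
    """10x10 grid over a 1x1 degree extent."""
    return GridSpec.from_bounds(10.0, 40.0, 11.0, 41.0, 0.1)


@pytest.fixture
def fine_grid():
    """60x60 grid at 30 arcseconds over a 0.5 degree extent."""
    return GridSpec.from_bounds(0.0, 0.0, 0.5, 0.5, 1.0 / 120.0)


def random_class_grid(grid, seed):
    from chscreen.combine import ClassGrid

    rng = np.random.default_rng(seed)
    vals = rng.choice([0, 1, 10], size=grid.shape, p=[0.6, 0.2, 0.2])
    return ClassGrid(grid, vals.astype(np.uint8))
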