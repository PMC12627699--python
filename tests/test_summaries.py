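"""Geodesic areas, coverage reports, change analysis, sensitivity sweeps."""

import math

import numpy as np
import pytest
from scipy import integrate

from chscreen import (
    ClassGrid,
    Comparator,
    FractionRaster,
    GridSpec,
    Registry,
    cell_areas,
    class_coverage,
    compare_layers,
    criteria_coverage,
    encode_combinations,
    feature_change_composition,
    gen_range_set,
    threshold_sweep,
    trim_sweep,
)
from chscreen.binarize import BinaryLayer
from chscreen.summaries import (
    AUTHALIC_RADIUS_KM,
    WGS84_A_KM,
    WGS84_E2,
    CHANGE_CODES,
    ChangeCategory,
)

from conftest import make_trigger, random_class_grid


class TestCellAreas:
    def test_global_sphere_sums_to_4piR2(self):
        grid = GridSpec.from_bounds(-180, -90, 180, 90, 1.0)
        total = cell_areas(grid, "sphere").total
        expect = 4 * math.pi * AUTHALIC_RADIUS_KM**2
        assert abs(total - expect) / expect < 1e-9

    def test_equator_mirror_symmetry(self):
        grid = GridSpec.from_bounds(0, -10, 10, 10, 1.0)
        a = cell_areas(grid).cell_area_km2
        assert np.allclose(a, a[::-1], rtol=1e-12)

    def test_area_constant_along_rows(self):
        grid = GridSpec.from_bounds(0, 0, 10, 10, 1.0)
        a = cell_areas(grid).cell_area_km2
        assert (a == a[:, [0]]).all()

    @pytest.mark.parametrize("model", ["sphere", "spheroid"])
    def test_equatorial_30arcsec_cell_matches_quadrature(self, model):
        """One 30-arcsecond cell at the equator against direct numeric
        integration of the surface-area element."""
        s = 1.0 / 120.0
        grid = GridSpec.from_bounds(0, 0, s, s, s)
        cell = cell_areas(grid, model).cell_area_km2[0, 0]
        dlam = math.radians(s)
        if model == "sphere":
            f = lambda phi: AUTHALIC_RADIUS_KM**2 * math.cos(phi)
        else:
            f = lambda phi: (
                WGS84_A_KM**2
                * (1 - WGS84_E2)
                * math.cos(phi)
                / (1 - WGS84_E2 * math.sin(phi) ** 2) ** 2
            )
        oracle, _ = integrate.quad(f, 0.0, math.radians(s))
        oracle *= dlam
        assert cell == pytest.approx(oracle, rel=1e-9)

    def test_spheroid_total_close_to_known_surface_area(self):
        # WGS 84 surface area is about 510.066 million km^2
        grid = GridSpec.from_bounds(-180, -90, 180, 90, 1.0)
        total = cell_areas(grid, "spheroid").total
        assert total == pytest.approx(510.0656e6, rel=1e-4)


class TestClassCoverage:
    def test_uniform_likely(self, small_grid):
        vals = np.full(small_grid.shape, 10, dtype=np.uint8)
        cov = class_coverage(ClassGrid(small_grid, vals), cell_areas(small_grid))
        likely = cov[cov.ch_class == "Likely"].iloc[0]
        assert likely.pct_of_zone == pytest.approx(100.0)
        assert likely.pct_within_class == pytest.approx(100.0)

    def test_two_zone_split(self, small_grid):
        vals = np.zeros(small_grid.shape, dtype=np.uint8)
        vals[:, :5] = 10  # Likely only in zone A (west half)
        zones = np.where(
            np.arange(small_grid.n_cols) < 5, "A", "B"
        )[None, :].repeat(small_grid.n_rows, axis=0)
        cov = class_coverage(ClassGrid(small_grid, vals), cell_areas(small_grid), zones)
        la = cov[(cov.zone == "A") & (cov.ch_class == "Likely")].iloc[0]
        lb = cov[(cov.zone == "B") & (cov.ch_class == "Likely")].iloc[0]
        assert la.pct_within_class == pytest.approx(100.0)
        assert lb.pct_within_class == pytest.approx(0.0)

    def test_matches_per_cell_accumulation(self, small_grid):
        cgrid = random_class_grid(small_grid, 3)
        areas = cell_areas(small_grid)
        cov = class_coverage(cgrid, areas)
        for code, name in [(0, "Unclassified"), (1, "Potential"), (10, "Likely")]:
            brute = sum(
                areas.cell_area_km2[r, c]
                for r in range(small_grid.n_rows)
                for c in range(small_grid.n_cols)
                if cgrid.values[r, c] == code
            )
            got = cov[cov.ch_class == name].area_km2.iloc[0]
            assert got == pytest.approx(brute, rel=1e-12)

    def test_conservation(self, small_grid):
        cgrid = random_class_grid(small_grid, 4)
        areas = cell_areas(small_grid)
        cov = class_coverage(cgrid, areas)
        assert cov.area_km2.sum() == pytest.approx(areas.total, rel=1e-9)


class TestCriteriaCoverage:
    def test_single_trigger_two_criteria_sums_to_200pct(self, small_grid):
        registry = Registry((make_trigger("L_A", criteria=(1, 4)),))
        mask = np.zeros(small_grid.shape, bool)
        mask[:3, :] = True
        cg = encode_combinations([BinaryLayer("L_A", small_grid, mask)], registry)
        table = criteria_coverage(cg, cell_areas(small_grid))
        likely = table[table.ch_class == "Likely"]
        assert set(likely.criterion) == {1, 4}
        assert likely.pct_of_class.sum() == pytest.approx(200.0)

    def test_no_classified_cells_empty(self, small_grid):
        registry = Registry((make_trigger("L_A"),))
        cg = encode_combinations(
            [BinaryLayer("L_A", small_grid, np.zeros(small_grid.shape, bool))],
            registry,
        )
        assert criteria_coverage(cg, cell_areas(small_grid)).empty

    def test_per_criterion_area_bounded_by_class_area(self, small_grid):
        registry = Registry(
            (
                make_trigger("L_A", criteria=(1, 4)),
                make_trigger("P_B", criteria=(3, 4)),
            )
        )
        rng = np.random.default_rng(7)
        layers = [
            BinaryLayer(c, small_grid, rng.integers(0, 2, small_grid.shape).astype(bool))
            for c in registry.shortcodes
        ]
        areas = cell_areas(small_grid)
        cg = encode_combinations(layers, registry)
        table = criteria_coverage(cg, areas)
        from chscreen import to_basic

        basic = to_basic(cg)
        for name in ("Likely", "Potential"):
            code = 10 if name == "Likely" else 1
            class_area = float(areas.cell_area_km2[basic.values == code].sum())
            sub = table[table.ch_class == name]
            assert (sub.area_km2 <= class_area + 1e-9).all()


class TestCompareLayers:
    def test_identity_only_never_and_no_change(self, small_grid):
        cgrid = random_class_grid(small_grid, 11)
        areas = cell_areas(small_grid)
        change, table = compare_layers(cgrid, cgrid, areas)
        moved = table[table.category.isin(["added", "upgraded", "downgraded", "removed"])]
        assert (moved.area_km2 == 0).all()

    def test_all_added(self, small_grid):
        zero = ClassGrid(small_grid, np.zeros(small_grid.shape, np.uint8))
        ten = ClassGrid(small_grid, np.full(small_grid.shape, 10, np.uint8))
        areas = cell_areas(small_grid)
        _, table = compare_layers(zero, ten, areas)
        added = table[table.category == "added"].area_km2.iloc[0]
        assert added == pytest.approx(areas.total, rel=1e-12)

    def test_category_tally_matches_per_cell(self, small_grid):
        old = random_class_grid(small_grid, 21)
        new = random_class_grid(small_grid, 22)
        areas = cell_areas(small_grid)
        change, table = compare_layers(old, new, areas)

        def expected_cat(o, n):
            if o == 0 and n == 0:
                return "never"
            if o == n:
                return "no_change"
            if o == 0:
                return "added"
            if n == 0:
                return "removed"
            return "upgraded" if n > o else "downgraded"

        brute: dict[str, float] = {}
        for r in range(small_grid.n_rows):
            for c in range(small_grid.n_cols):
                cat = expected_cat(old.values[r, c], new.values[r, c])
                brute[cat] = brute.get(cat, 0.0) + areas.cell_area_km2[r, c]
        for _, row in table.iterrows():
            assert row.area_km2 == pytest.approx(
                brute.get(row.category, 0.0), rel=1e-12, abs=1e-12
            )

    def test_antisymmetry(self, small_grid):
        old = random_class_grid(small_grid, 31)
        new = random_class_grid(small_grid, 32)
        areas = cell_areas(small_grid)
        _, fwd = compare_layers(old, new, areas)
        _, rev = compare_layers(new, old, areas)
        f = fwd.set_index("category").area_km2
        r = rev.set_index("category").area_km2
        assert f["added"] == pytest.approx(r["removed"])
        assert f["removed"] == pytest.approx(r["added"])
        assert f["upgraded"] == pytest.approx(r["downgraded"])
        assert f["downgraded"] == pytest.approx(r["upgraded"])
        assert f["no_change"] == pytest.approx(r["no_change"])
        assert f["never"] == pytest.approx(r["never"])


class TestFeatureChangeComposition:
    def test_full_coverage_trigger_is_100pct(self, small_grid):
        zero = ClassGrid(small_grid, np.zeros(small_grid.shape, np.uint8))
        ten = ClassGrid(small_grid, np.full(small_grid.shape, 10, np.uint8))
        areas = cell_areas(small_grid)
        change, _ = compare_layers(zero, ten, areas)
        layer = BinaryLayer("L_A", small_grid, np.ones(small_grid.shape, bool))
        table = feature_change_composition(change, [layer], areas)
        added = table[(table.shortcode == "L_A") & (table.category == "added")].iloc[0]
        assert added.pct_of_category_area == pytest.approx(100.0)
        assert added.pct_of_feature_area == pytest.approx(100.0)

    def test_copresent_triggers_sum_over_100(self, small_grid):
        """Two triggers covering every added cell each account for 100% of
        the added area — per-category percentages exceed 100 in sum."""
        zero = ClassGrid(small_grid, np.zeros(small_grid.shape, np.uint8))
        ten = ClassGrid(small_grid, np.full(small_grid.shape, 10, np.uint8))
        areas = cell_areas(small_grid)
        change, _ = compare_layers(zero, ten, areas)
        layers = [
            BinaryLayer("L_A", small_grid, np.ones(small_grid.shape, bool)),
            BinaryLayer("L_B", small_grid, np.ones(small_grid.shape, bool)),
        ]
        table = feature_change_composition(change, layers, areas)
        added = table[table.category == "added"]
        assert added.pct_of_category_area.sum() == pytest.approx(200.0)

    def test_matches_brute_force(self, small_grid):
        old = random_class_grid(small_grid, 41)
        new = random_class_grid(small_grid, 42)
        areas = cell_areas(small_grid)
        change, _ = compare_layers(old, new, areas)
        rng = np.random.default_rng(43)
        mask = rng.integers(0, 2, small_grid.shape).astype(bool)
        layer = BinaryLayer("L_A", small_grid, mask)
        table = feature_change_composition(change, [layer], areas)
        for cat, code in CHANGE_CODES.items():
            brute = float(
                areas.cell_area_km2[mask & (change.category == code)].sum()
            )
            got = table[
                (table.shortcode == "L_A") & (table.category == cat.value)
            ].area_km2.iloc[0]
            assert got == pytest.approx(brute, rel=1e-12, abs=1e-12)


class TestSweeps:
    def test_constant_raster_thresholds(self, small_grid):
        fr = FractionRaster(small_grid, np.full(small_grid.shape, 0.6))
        table = threshold_sweep(
            fr, [0.25, 0.5, 0.75, 0.9], Comparator.GE, cell_areas(small_grid)
        )
        assert list(table.pct_of_grid.round(9)) == [100.0, 100.0, 0.0, 0.0]

    def test_monotone_non_increasing(self, small_grid):
        rng = np.random.default_rng(5)
        fr = FractionRaster(small_grid, rng.uniform(0, 1, small_grid.shape))
        table = threshold_sweep(
            fr, [0.25, 0.5, 0.75, 0.9], Comparator.GE, cell_areas(small_grid)
        )
        assert (np.diff(table.area_km2) <= 0).all()

    def test_matches_brute_force_counts(self, small_grid):
        rng = np.random.default_rng(6)
        vals = rng.uniform(0, 1, small_grid.shape)
        fr = FractionRaster(small_grid, vals)
        areas = cell_areas(small_grid)
        table = threshold_sweep(fr, [0.25, 0.5], Comparator.GE, areas)
        for _, row in table.iterrows():
            brute = float(areas.cell_area_km2[vals >= row.threshold].sum())
            assert row.area_km2 == pytest.approx(brute, rel=1e-12)

    def test_trim_sweep_monotone(self):
        ranges = gen_range_set(seed=2, n_ranges=80, n_outliers=2,
                               outlier_multiplier=1000.0)
        table = trim_sweep(ranges)
        assert (np.diff(table.n_removed) <= 0).all()
        assert (np.diff(table.pct_area_retained) >= 0).all()

    def test_trim_sweep_all_equal(self):
        ranges = [(i, 3.0, None) for i in range(10)]
        table = trim_sweep(ranges)
        assert (table.n_removed == 0).all()
        assert (table.pct_area_retained == 100.0).all()

    def test_extreme_outlier_removed_at_3sd(self):
        areas = [1.0] * 50 + [1e6]
        ranges = [(i, a, None) for i, a in enumerate(areas)]
        table = trim_sweep(ranges, ks=(3, 10))
        assert table[table.k == 3].n_removed.iloc[0] == 1
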