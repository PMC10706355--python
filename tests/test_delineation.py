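"""Radius search: analytic recovery, scan/fast equivalence, flags."""

import math

import numpy as np
import pytest

from foodshed import (
    GeoUnit,
    LandType,
    SearchConfig,
    build_distance_index,
    delineate,
    delineate_fast,
    delineate_unit,
    self_sufficiency,
)
from foodshed.errors import DelineationError, UndefinedRatioError
from conftest import make_fraction_grid, uniform_grid


def _whole_grid_unit(grid, population=1.0):
    return GeoUnit("u", "U", population, grid.extent)


# -- analytic recovery ------------------------------------------------------


def test_full_cover_recovers_analytic_radius():
    """Demand pi*r^2 on full cover must return radius r (within one search
    step plus discretization)."""
    grid = uniform_grid(200, 50)  # 10 km x 10 km, 50 m cells
    unit = _whole_grid_unit(grid)
    demand = math.pi * 2.0**2
    res = delineate(unit, demand, grid, LandType.ARABLE)
    assert res.met
    assert res.radius_km == pytest.approx(2.0, abs=0.02)


@pytest.mark.parametrize("fraction", [0.25, 0.5])
def test_partial_cover_recovers_scaled_radius(fraction):
    """With uniform class fraction f the analytic radius is sqrt(D/(pi f))."""
    grid = make_fraction_grid(100, 100, fraction, seed=17)  # 10 km side
    unit = _whole_grid_unit(grid)
    demand = 3.0
    expected = math.sqrt(demand / (math.pi * fraction))
    tol = 0.01 + 2 * grid.cell_size_m / 1000.0
    res = delineate_unit(unit, demand, grid, LandType.ARABLE)
    assert res.met
    assert abs(res.radius_km - expected) <= tol


# -- scan vs index equivalence ----------------------------------------------


def test_fast_equals_scan_on_random_grids():
    """The first-crossing search on the cumulative curve returns the same
    radius and flags as the literal step scan."""
    rng = np.random.default_rng(123)
    for trial in range(10):
        grid = make_fraction_grid(50, 200, float(rng.uniform(0.1, 0.9)), seed=trial)
        unit = _whole_grid_unit(grid)
        total = grid.total_area_km2(LandType.ARABLE)
        demand = float(rng.uniform(0.01, 1.2 * total))
        a = delineate(unit, demand, grid, LandType.ARABLE)
        b = delineate_unit(unit, demand, grid, LandType.ARABLE)
        assert b.radius_km == pytest.approx(a.radius_km, abs=1e-12), trial
        assert b.met == a.met and b.restricted_to_boundary == a.restricted_to_boundary
        assert b.accumulated_km2 == pytest.approx(a.accumulated_km2)


def test_single_cell_demand_snaps_to_nearest_cell_distance():
    """3-by-3 grid, one eligible corner cell: the radius is the distance to
    that cell's center, snapped up to the 0.01 km step grid."""
    codes = np.zeros((3, 3), dtype=np.int8)
    codes[0, 0] = 1  # arable cell, center at (1000, 5000) for 2 km cells
    from foodshed import LandCoverGrid

    grid = LandCoverGrid(codes, cell_size_m=2000)
    unit = _whole_grid_unit(grid)
    cfg = SearchConfig(threshold_km2=0.0)
    demand = grid.cell_area_km2  # exactly one cell
    # center (3000, 3000) -> distance sqrt(2^2 + 2^2) = 2.8284 km -> 2.83
    expected = 1.0 + math.ceil((math.hypot(2, 2) - 1.0) / 0.01) * 0.01
    scan = delineate(unit, demand, grid, LandType.ARABLE, cfg)
    fast = delineate_unit(unit, demand, grid, LandType.ARABLE, cfg)
    assert scan.radius_km == pytest.approx(expected, abs=1e-9)
    assert fast.radius_km == pytest.approx(expected, abs=1e-9)


# -- degenerate and failure cases -------------------------------------------


def test_zero_demand_returns_empty_foodshed():
    grid = uniform_grid(10, 100)
    res = delineate(_whole_grid_unit(grid), 0.0, grid, LandType.ARABLE)
    assert res.radius_km == 0.0
    assert res.met
    assert res.self_sufficiency_pct is None


def test_unsatisfiable_demand_caps_at_max_radius():
    grid = make_fraction_grid(20, 100, 0.3, seed=3)
    unit = _whole_grid_unit(grid)
    demand = 2 * grid.total_area_km2(LandType.ARABLE) + 1.0
    scan = delineate(unit, demand, grid, LandType.ARABLE)
    fast = delineate_unit(unit, demand, grid, LandType.ARABLE)
    for res in (scan, fast):
        assert not res.met
        assert res.radius_km == pytest.approx(scan.radius_km)


def test_empty_class_with_demand_is_unmet():
    grid = uniform_grid(10, 100, LandType.ARABLE)
    res = delineate_unit(_whole_grid_unit(grid), 1.0, grid, LandType.WATERS)
    assert not res.met


def test_centroid_outside_grid_raises():
    from shapely.geometry import box

    grid = uniform_grid(10, 100)
    unit = GeoUnit("far", "Far", 1.0, box(5e5, 5e5, 6e5, 6e5))
    with pytest.raises(DelineationError):
        delineate(unit, 1.0, grid, LandType.ARABLE)


# -- boundary restriction ---------------------------------------------------


def test_sufficient_boundary_restricts_accumulation():
    """When in-boundary area covers demand, the final circle only counts
    in-boundary cells and the SSR is at least 100%."""
    from shapely.geometry import box

    grid = uniform_grid(100, 100)  # 10 km x 10 km, all arable
    inner = box(2000, 2000, 8000, 8000)  # 36 km2 available
    unit = GeoUnit("inner", "Inner", 1.0, inner)
    res = delineate_unit(unit, 30.0, grid, LandType.ARABLE)
    assert res.restricted_to_boundary
    assert res.self_sufficiency_pct >= 100.0
    assert res.accumulated_km2 <= res.available_km2 + 1e-9
    # the full-grid circle at the same radius would hold more area
    unrestricted = build_distance_index(grid, inner.centroid, LandType.ARABLE)
    assert unrestricted.area_at(res.radius_km) > res.accumulated_km2


def test_insufficient_boundary_spills_into_hinterland():
    from shapely.geometry import box

    grid = uniform_grid(100, 100)
    small = box(4000, 4000, 5000, 5000)  # 1 km2 available
    unit = GeoUnit("small", "Small", 1.0, small)
    res = delineate_unit(unit, 25.0, grid, LandType.ARABLE)
    assert not res.restricted_to_boundary
    assert res.met
    assert res.self_sufficiency_pct == pytest.approx(4.0)  # 1/25
    assert res.accumulated_km2 > res.available_km2


# -- monotonicity -----------------------------------------------------------

def test_radius_nondecreasing_in_demand():
    grid = make_fraction_grid(60, 150, 0.4, seed=29)
    unit = _whole_grid_unit(grid)
    total = grid.total_area_km2(LandType.ARABLE)
    radii = [
        delineate_unit(unit, d, grid, LandType.ARABLE).radius_km
        for d in np.linspace(0.1, 0.9 * total, 8)
    ]
    assert all(r2 >= r1 for r1, r2 in zip(radii, radii[1:]))


def test_radius_nonincreasing_in_class_fraction():
    demand = 4.0
    radii = []
    for f in (0.2, 0.4, 0.8):
        grid = make_fraction_grid(80, 150, f, seed=31)
        res = delineate_unit(_whole_grid_unit(grid), demand, grid, LandType.ARABLE)
        radii.append(res.radius_km)
    assert all(r2 <= r1 for r1, r2 in zip(radii, radii[1:]))


# -- self-sufficiency ratio -------------------------------------------------


@pytest.mark.parametrize(
    "available,demand,expected",
    [(5.0, 5.0, 100.0), (0.0, 3.0, 0.0), (10.0, 5.0, 200.0)],
)
def test_self_sufficiency_ratio(available, demand, expected):
    assert self_sufficiency(available, demand) == pytest.approx(expected)


def test_self_sufficiency_undefined_for_zero_demand():
    with pytest.raises(UndefinedRatioError):
        self_sufficiency(1.0, 0.0)
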