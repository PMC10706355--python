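"""Reclassification, cell-center area accounting and the distance index."""

import logging
import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from foodshed import (
    LandCoverGrid,
    LandType,
    area_within_circle,
    area_within_polygon,
    build_distance_index,
    read_ascii_grid,
    read_boundaries_geojson,
    reclassify,
    write_ascii_grid,
    write_boundaries_geojson,
)
from foodshed.errors import ValidationError
from conftest import make_fraction_grid, uniform_grid


# -- reclassification -------------------------------------------------------


def test_reclassify_single_code():
    grid = reclassify(
        np.ones((4, 4), dtype=int), {1: LandType.ARABLE}, cell_size_m=100
    )
    assert grid.class_mask(LandType.ARABLE).all()


def test_unmapped_code_default_none_excluded_from_areas():
    raw = np.array([[1, 9], [9, 1]])
    grid = reclassify(raw, {1: "arable"}, cell_size_m=1000, unmapped="none")
    assert grid.total_area_km2(LandType.ARABLE) == 2.0
    assert sum(grid.class_fractions().values()) == 0.5


def test_unmapped_code_without_default_raises():
    with pytest.raises(ValidationError):
        reclassify(np.array([[1, 9]]), {1: "arable"}, cell_size_m=100)


def test_mixed_codes_match_hand_count():
    rng = np.random.default_rng(11)
    raw = rng.integers(1, 5, size=(8, 8))
    class_map = {1: "arable", 2: "horticultural", 3: "waters", 4: None}
    grid = reclassify(raw, class_map, cell_size_m=500)
    for code, target in [(1, LandType.ARABLE), (2, LandType.HORTICULTURAL),
                         (3, LandType.WATERS)]:
        hand = int((raw == code).sum())  # brute-force count
        assert int(grid.class_mask(target).sum()) == hand


def test_geographic_crs_rejected():
    with pytest.raises(ValidationError, match="projected"):
        LandCoverGrid(np.zeros((2, 2)), cell_size_m=30, crs_tag="EPSG:4326")


# -- polygon areas ----------------------------------------------------------


def test_polygon_covering_grid_counts_total_class_area():
    grid = make_fraction_grid(20, 100, 0.4, seed=5)
    hull = grid.extent.buffer(10)
    assert area_within_polygon(grid, hull, LandType.ARABLE) == pytest.approx(
        grid.total_area_km2(LandType.ARABLE)
    )


def test_disjoint_polygon_gives_zero_with_warning(caplog):
    grid = uniform_grid(5, 100)
    far = box(1e6, 1e6, 1e6 + 10, 1e6 + 10)
    with caplog.at_level(logging.WARNING, logger="foodshed.geodata"):
        assert area_within_polygon(grid, far, LandType.ARABLE) == 0.0
    assert any("disjoint" in rec.message for rec in caplog.records)


def test_random_polygon_matches_per_cell_point_in_polygon_oracle():
    rng = np.random.default_rng(2)
    grid = make_fraction_grid(20, 100, 0.5, seed=2)
    poly = Polygon(
        [(200, 300), (1800, 150), (1500, 1700), (900, 1100), (100, 1600)]
    )
    # brute force: test every cell center individually
    xs, ys = grid.cell_centers()
    sel = grid.class_mask(LandType.ARABLE).ravel()
    expected = sum(
        1
        for x, y, s in zip(xs, ys, sel)
        if s and poly.contains(Point(x, y))
    ) * grid.cell_area_km2
    assert area_within_polygon(grid, poly, LandType.ARABLE) == pytest.approx(expected)


# -- circle areas -----------------------------------------------------------


def test_zero_radius_circle_is_empty():
    grid = uniform_grid(10, 100)
    assert area_within_circle(grid, (500.0, 500.0), 0.0, LandType.ARABLE) == 0.0


def test_huge_radius_covers_everything():
    grid = make_fraction_grid(15, 200, 0.3, seed=9)
    area = area_within_circle(grid, (1500.0, 1500.0), 1e4, LandType.ARABLE)
    assert area == pytest.approx(grid.total_area_km2(LandType.ARABLE))


def test_circle_area_approaches_pi_r_squared():
    """On full cover, the cell-center count converges to the true circle
    area; at 50 m cells a 2 km circle is within 1%."""
    grid = uniform_grid(200, 50)  # 10 km x 10 km
    center = (5000.0, 5000.0)
    area = area_within_circle(grid, center, 2.0, LandType.ARABLE)
    assert area == pytest.approx(math.pi * 4.0, rel=0.01)


def test_cell_center_rule_converges_with_resolution():
    truth = math.pi * 4.0
    errors = []
    for n, cell in [(100, 100), (400, 25)]:
        grid = uniform_grid(n, cell)
        c = (n * cell / 2, n * cell / 2)
        errors.append(abs(area_within_circle(grid, c, 2.0, LandType.ARABLE) - truth))
    assert errors[1] < errors[0]


def test_circle_area_monotone_in_radius():
    grid = make_fraction_grid(30, 150, 0.4, seed=13)
    center = (2250.0, 2250.0)
    radii = np.linspace(0, 5, 40)
    areas = [area_within_circle(grid, center, r, LandType.ARABLE) for r in radii]
    assert all(a2 >= a1 for a1, a2 in zip(areas, areas[1:]))


# -- distance index ---------------------------------------------------------


def test_empty_class_gives_empty_index():
    grid = uniform_grid(5, 100, LandType.ARABLE)
    idx = build_distance_index(grid, (250.0, 250.0), LandType.WATERS)
    assert idx.n_cells == 0
    assert idx.area_at(100.0) == 0.0
    assert idx.radius_for_area(1.0) is None


def test_index_query_equals_direct_circle_scan():
    grid = make_fraction_grid(10, 100, 0.6, seed=21)
    center = (430.0, 510.0)
    idx = build_distance_index(grid, center, LandType.ARABLE)
    rng = np.random.default_rng(1)
    for r in rng.uniform(0.05, 2.0, size=5):
        assert idx.area_at(r) == area_within_circle(
            grid, center, r, LandType.ARABLE
        )


def test_masked_index_total_equals_polygon_area():
    grid = make_fraction_grid(25, 100, 0.5, seed=4)
    mask = box(300, 300, 1900, 2100)
    idx = build_distance_index(grid, (1000.0, 1000.0), LandType.ARABLE, mask)
    assert idx.total_area_km2 == pytest.approx(
        area_within_polygon(grid, mask, LandType.ARABLE)
    )


def test_index_cumulative_is_consistent():
    grid = make_fraction_grid(12, 250, 0.5, seed=6)
    idx = build_distance_index(grid, (10.0, 20.0), LandType.ARABLE)
    assert np.all(np.diff(idx.distances_km) >= 0)
    assert idx.area_at(np.inf) == pytest.approx(
        grid.total_area_km2(LandType.ARABLE), rel=1e-9
    )


# -- I/O --------------------------------------------------------------------


def test_ascii_grid_roundtrip(tmp_path):
    grid = make_fraction_grid(9, 123.0, 0.4, seed=8)
    path = tmp_path / "grid.asc"
    write_ascii_grid(grid, path)
    back = read_ascii_grid(path)
    assert np.array_equal(back.classes, grid.classes)
    assert back.cell_size_m == pytest.approx(grid.cell_size_m)
    assert back.x_origin == pytest.approx(grid.x_origin)
    assert back.y_origin == pytest.approx(grid.y_origin)
    assert back.crs_tag == grid.crs_tag


def test_boundaries_geojson_roundtrip(tmp_path):
    geoms = {"a": box(0, 0, 100, 100), "b": box(100, 0, 250, 100)}
    path = tmp_path / "units.geojson"
    write_boundaries_geojson(geoms, path)
    back = read_boundaries_geojson(path)
    assert set(back) == {"a", "b"}
    for uid in geoms:
        assert back[uid].equals(geoms[uid])
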