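"""Foodshed delineation by radial accumulation, and self-sufficiency.

A geo-unit's foodshed for one land type is the smallest circle, centered
on the unit's centroid, whose enclosed agricultural area of that type
meets the unit's demand. The search starts at a 1 km radius and grows in
0.01 km steps until the accumulated class area is within a slack
threshold of the demand. Two situations are distinguished:

* the unit's own boundary already contains enough class area — the
  accumulation is then restricted to in-boundary cells (the foodshed is
  internal), or
* it does not — every grid cell is eligible and the circle spills into
  the hinterland.

Self-sufficiency is the ratio of in-boundary available area to demanded
area, in percent; 100% or more implies theoretical export capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from shapely.geometry import Point

from .demand import GeoUnit
from .errors import DelineationError, UndefinedRatioError, ValidationError
from .footprint import LandType
from .geodata import (
    DistanceIndex,
    LandCoverGrid,
    area_within_circle,
    area_within_polygon,
    build_distance_index,
)


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the radius search.

    ``threshold_km2`` is the absolute slack on the accumulated-vs-demanded
    comparison; None means one grid-cell area (the finest resolvable
    slack). ``max_radius_km`` caps the search; None means the grid
    diagonal, which guarantees termination on insufficient grids.
    """

    initial_radius_km: float = 1.0
    step_km: float = 0.01
    threshold_km2: float | None = None
    max_radius_km: float | None = None
    use_representative_point: bool = False

    def __post_init__(self) -> None:
        if not self.step_km > 0:
            raise ValidationError("step_km must be > 0")
        if self.threshold_km2 is not None and self.threshold_km2 < 0:
            raise ValidationError("threshold_km2 must be >= 0")
        if (
            self.max_radius_km is not None
            and self.max_radius_km <= self.initial_radius_km
        ):
            raise ValidationError("max_radius_km must exceed initial_radius_km")


@dataclass(frozen=True)
class FoodshedResult:
    """Outcome of a delineation for one (geo-unit, land type) pair."""

    unit_id: str
    land_type: LandType
    demand_km2: float
    available_km2: float  # class area inside the unit's own boundary
    radius_km: float
    accumulated_km2: float  # class area inside the final circle
    self_sufficiency_pct: float | None  # None when demand is zero
    restricted_to_boundary: bool
    met: bool


def self_sufficiency(available_km2: float, demand_km2: float) -> float:
    """100 × available / demand. Demand must be strictly positive."""
    if demand_km2 <= 0:
        raise UndefinedRatioError(
            "self-sufficiency is undefined for zero demand"
        )
    return 100.0 * available_km2 / demand_km2


def _resolve(grid: LandCoverGrid, cfg: SearchConfig) -> tuple[float, float]:
    """Effective (threshold_km2, max_radius_km) for this grid."""
    threshold = (
        cfg.threshold_km2 if cfg.threshold_km2 is not None else grid.cell_area_km2
    )
    if cfg.max_radius_km is not None:
        max_radius = cfg.max_radius_km
    else:
        minx, miny, maxx, maxy = grid.extent.bounds
        max_radius = math.hypot(maxx - minx, maxy - miny) / 1000.0
    return threshold, max_radius


def _center(unit: GeoUnit, grid: LandCoverGrid, cfg: SearchConfig) -> Point:
    boundary = unit.boundary
    if boundary is None:
        raise DelineationError(f"{unit.unit_id}: geo-unit has no boundary")
    center = (
        boundary.representative_point()
        if cfg.use_representative_point
        else boundary.centroid
    )
    if not grid.extent.covers(center):
        raise DelineationError(
            f"{unit.unit_id}: centroid {center.wkt} falls outside the grid extent"
        )
    return center


def delineate(
    unit: GeoUnit,
    demand_km2: float,
    grid: LandCoverGrid,
    land_type: LandType,
    cfg: SearchConfig = SearchConfig(),
) -> FoodshedResult:
    """Step-scan radius search, the literal accumulate-and-grow loop."""
    if demand_km2 < 0:
        raise ValidationError("demand_km2 must be >= 0")
    center = _center(unit, grid, cfg)
    threshold, max_radius = _resolve(grid, cfg)
    available = area_within_polygon(grid, unit.boundary, land_type)
    restricted = available >= demand_km2
    ssr = self_sufficiency(available, demand_km2) if demand_km2 > 0 else None

    if demand_km2 <= 0:
        return FoodshedResult(
            unit.unit_id, land_type, demand_km2, available, 0.0, 0.0,
            ssr, restricted, True,
        )

    mask = unit.boundary if restricted else None
    target = demand_km2 - threshold
    k = 0
    radius = cfg.initial_radius_km
    met = True
    while True:
        accumulated = area_within_circle(grid, center, radius, land_type, mask)
        if accumulated >= target:
            break
        if radius >= max_radius:
            met = False
            radius = max_radius
            accumulated = area_within_circle(grid, center, radius, land_type, mask)
            break
        k += 1
        radius = min(cfg.initial_radius_km + k * cfg.step_km, max_radius)

    return FoodshedResult(
        unit.unit_id, land_type, demand_km2, available, radius, accumulated,
        ssr, restricted, met,
    )


def delineate_fast(
    unit: GeoUnit,
    demand_km2: float,
    index: DistanceIndex,
    cfg: SearchConfig = SearchConfig(),
    *,
    available_km2: float | None = None,
    land_type: LandType = LandType.ARABLE,
    max_radius_km: float | None = None,
) -> FoodshedResult:
    """First-crossing search on a precomputed cumulative-area curve.

    Returns the same radius and flags as :func:`delineate` for every
    input, provided ``index`` was built with the center, class and mask
    that :func:`delineate` would use (i.e. masked to the boundary iff the
    in-boundary area covers the demand). ``available_km2`` defaults to
    the index total, which is correct exactly when the index is masked.
    """
    if demand_km2 < 0:
        raise ValidationError("demand_km2 must be >= 0")
    available = (
        available_km2 if available_km2 is not None else index.total_area_km2
    )
    restricted = available >= demand_km2
    ssr = self_sufficiency(available, demand_km2) if demand_km2 > 0 else None
    threshold = (
        cfg.threshold_km2 if cfg.threshold_km2 is not None else index.cell_area_km2
    )

    if demand_km2 <= 0:
        return FoodshedResult(
            unit.unit_id, land_type, demand_km2, available, 0.0, 0.0,
            ssr, restricted, True,
        )

    max_radius = max_radius_km if max_radius_km is not None else float("inf")
    target = demand_km2 - threshold
    crossing = index.radius_for_area(target)
    if crossing is None:
        radius, met = max_radius, False
    else:
        if crossing <= cfg.initial_radius_km:
            radius = cfg.initial_radius_km
        else:
            # snap the crossing distance UP to the step grid
            steps = math.ceil(
                (crossing - cfg.initial_radius_km) / cfg.step_km - 1e-9
            )
            radius = cfg.initial_radius_km + steps * cfg.step_km
        met = radius <= max_radius
        if not met:
            radius = max_radius
    if not math.isfinite(radius):
        raise ValidationError(
            "demand exceeds the class total and no max_radius_km was given"
        )
    accumulated = index.area_at(radius)
    return FoodshedResult(
        unit.unit_id, land_type, demand_km2, available, radius, accumulated,
        ssr, restricted, met,
    )


def delineate_unit(
    unit: GeoUnit,
    demand_km2: float,
    grid: LandCoverGrid,
    land_type: LandType,
    cfg: SearchConfig = SearchConfig(),
) -> FoodshedResult:
    """Delineate via the distance index (production path).

    Builds the index with the mask :func:`delineate` would choose, then
    runs the first-crossing search. Scan and index paths are equivalent;
    this one does the area accounting once instead of per step.
    """
    if demand_km2 < 0:
        raise ValidationError("demand_km2 must be >= 0")
    center = _center(unit, grid, cfg)
    threshold, max_radius = _resolve(grid, cfg)
    available = area_within_polygon(grid, unit.boundary, land_type)
    restricted = available >= demand_km2
    mask = unit.boundary if restricted else None
    index = build_distance_index(grid, center, land_type, mask)
    eff_cfg = SearchConfig(
        initial_radius_km=cfg.initial_radius_km,
        step_km=cfg.step_km,
        threshold_km2=threshold,
        max_radius_km=None,
        use_representative_point=cfg.use_representative_point,
    )
    result = delineate_fast(
        unit,
        demand_km2,
        index,
        eff_cfg,
        available_km2=available,
        land_type=land_type,
        max_radius_km=max_radius,
    )
    return result
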