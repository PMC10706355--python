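"""Scaling per-capita land demand to geo-units and regions.

Total demand is linear in population:

    LD_total = LD_per_capita * POP_total

with per-capita demand in m²/capita and totals reported in km².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .errors import LookupError_, UndefinedRatioError, ValidationError
from .footprint import LandType, PerCapitaDemand

M2_PER_KM2 = 1e6

#: population file unit used by the shipped regional fixture (10⁴ persons)
DEFAULT_POPULATION_UNIT = 1e4


@dataclass
class GeoUnit:
    """An administrative unit: id, boundary polygon, population.

    ``population`` is stored in persons (the CSV loader applies the
    ``population_unit`` multiplier). ``boundary`` may be None for purely
    tabular work (e.g. demand accounting without delineation).
    """

    unit_id: str
    name: str
    population: float
    boundary: BaseGeometry | None = None

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValidationError(
                f"{self.unit_id}: population must be >= 0, got {self.population}"
            )
        if self.boundary is not None and not self.boundary.is_valid:
            raise ValidationError(f"{self.unit_id}: boundary polygon is invalid")

    @property
    def centroid(self) -> Point:
        if self.boundary is None:
            raise ValidationError(f"{self.unit_id}: no boundary, no centroid")
        return self.boundary.centroid


def total_demand(per_capita: PerCapitaDemand, unit: GeoUnit) -> dict[LandType, float]:
    """Per-land-type total demand in km² for one geo-unit."""
    if unit.population < 0:  # defence in depth; GeoUnit already validates
        raise ValidationError("population must be >= 0")
    return {
        lt: per_capita[lt] * unit.population / M2_PER_KM2 for lt in LandType
    }


@dataclass
class DemandTable:
    """Per (unit, land type) demand in km², as a tidy DataFrame.

    The frame is indexed by ``unit_id`` with one column per land type.
    """

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_units(
        cls, per_capita: PerCapitaDemand, units: Iterable[GeoUnit]
    ) -> "DemandTable":
        rows = {
            u.unit_id: {lt.value: d for lt, d in total_demand(per_capita, u).items()}
            for u in units
        }
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame = frame[[lt.value for lt in LandType]]
        frame.index.name = "unit_id"
        return cls(frame)

    def demand(self, unit_id: str, land_type: LandType) -> float:
        if unit_id not in self.frame.index:
            raise LookupError_(f"unknown unit {unit_id!r}")
        return float(self.frame.loc[unit_id, land_type.value])

    def aggregate_region(
        self, member_ids: Sequence[str] | None = None
    ) -> dict[LandType, float]:
        """Element-wise sum of member rows (all rows when ids omitted)."""
        if member_ids is None:
            sub = self.frame
        else:
            missing = [m for m in member_ids if m not in self.frame.index]
            if missing:
                raise LookupError_(f"unknown unit ids: {missing}")
            sub = self.frame.loc[list(member_ids)]
        sums = sub.sum(axis=0)
        return {lt: float(sums[lt.value]) for lt in LandType}

    def with_region_row(
        self, region_id: str = "region", member_ids: Sequence[str] | None = None
    ) -> "DemandTable":
        totals = self.aggregate_region(member_ids)
        frame = self.frame.copy()
        frame.loc[region_id] = {lt.value: v for lt, v in totals.items()}
        return DemandTable(frame)


def demand_share(totals: dict[LandType, float], land_type: LandType) -> float:
    """One land type's percent share of total demand across all three."""
    total = sum(totals.values())
    if total <= 0:
        raise UndefinedRatioError("total demand is zero; share undefined")
    return 100.0 * totals[land_type] / total


def load_populations(
    path: str | Path, population_unit: float = DEFAULT_POPULATION_UNIT
) -> list[GeoUnit]:
    """Read ``unit_id, name, population`` CSV; populations are multiplied
    by ``population_unit`` into persons."""
    df = pd.read_csv(path, dtype={"unit_id": str, "name": str})
    return [
        GeoUnit(
            unit_id=row.unit_id,
            name=row.name,
            population=float(row.population) * population_unit,
        )
        for row in df.itertuples(index=False)
    ]
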