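"""Land footprint of food consumption.

Converts per-capita annual food consumption (kg/yr) into per-capita
agricultural-area demand (m²/capita/yr), split across three agricultural
land types: arable land, horticultural landscapes and waters.

The core relation is linear: for a plant food *i* grown directly on land,

    LD_i = FC_i * omega_i

where ``omega`` (ω, m² per kg) is the crop-to-land conversion factor, the
reciprocal of per-area yield. Animal products are produced from feed grown
on arable land, so their footprint divides by the feed conversion rate
``phi`` (φ, kg edible product per kg feed):

    LD_j = FC_j * omega_j / phi_j

Aquatic products occupy water surface directly *and* consume arable-grown
feed, so they carry two coefficients, one per land type.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import InvalidEntryError, LookupError_, ValidationError

logger = logging.getLogger(__name__)

#: food ids the fruit split maps a total "fruits" consumption onto
FRUIT_TOTAL_ID = "fruits"
FRUIT_FRESH_ID = "fruit_fresh"
FRUIT_DRIED_ID = "fruit_dried"

#: default share of fruit consumed fresh (regional diets here favour fresh fruit;
#: this is an assumption, exposed as a config parameter)
DEFAULT_FRUIT_FRESH_FRACTION = 0.9


class LandType(str, Enum):
    """The three agricultural land types every result is keyed by."""

    ARABLE = "arable"
    HORTICULTURAL = "horticultural"
    WATERS = "waters"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_CATEGORIES = {"crop", "animal", "aquatic", "fruit_fresh", "fruit_dried"}


@dataclass(frozen=True)
class ConversionEntry:
    """One food item's conversion coefficients.

    Parameters
    ----------
    food_id
        Identifier used to match consumption rows.
    category
        One of ``crop``, ``animal``, ``aquatic``, ``fruit_fresh``,
        ``fruit_dried``.
    omega
        Crop-to-land factor, m² of land per kg of (feed) crop.
    phi
        Feed conversion rate, kg edible food per kg feed. Required for
        ``animal`` and ``aquatic`` categories, absent otherwise.
    land_type
        Primary land type charged for this food.
    area_per_kg_override
        Printed coefficient that takes precedence over ``omega / phi``
        where a source table disagrees with the quotient; the computed
        value is logged as a warning when they differ.
    second_land_type, second_area_per_kg
        Second (land type, m²/kg) pair; aquatic products charge both a
        waters and an arable coefficient.
    """

    food_id: str
    category: str
    omega: float
    land_type: LandType
    phi: float | None = None
    area_per_kg_override: float | None = None
    second_land_type: LandType | None = None
    second_area_per_kg: float | None = None

    def __post_init__(self) -> None:
        if self.category not in _CATEGORIES:
            raise InvalidEntryError(
                f"{self.food_id}: unknown category {self.category!r}"
            )
        if not self.omega > 0:
            raise InvalidEntryError(f"{self.food_id}: omega must be > 0")
        if self.category in ("animal", "aquatic"):
            if self.phi is None or not self.phi > 0:
                raise InvalidEntryError(
                    f"{self.food_id}: category {self.category} requires phi > 0"
                )
        if self.area_per_kg_override is not None and not self.area_per_kg_override > 0:
            raise InvalidEntryError(f"{self.food_id}: override must be > 0")
        if self.category == "aquatic" and self.second_land_type is None:
            raise InvalidEntryError(
                f"{self.food_id}: aquatic entries need a second land-type pair"
            )

    @property
    def computed_area_per_kg(self) -> float:
        """ω for plant foods, ω/φ for fed (animal/aquatic) foods."""
        if self.category in ("animal", "aquatic"):
            return self.omega / self.phi  # type: ignore[operator]
        return self.omega


def area_per_kg(entry: ConversionEntry) -> list[tuple[LandType, float]]:
    """Agricultural area (m²) demanded per kg of this food, by land type.

    Plant foods pass ω through to their target land type. Animal foods
    charge ω/φ of arable land unless a printed override is configured, in
    which case the override wins and the ω/φ value is logged. Aquatic
    foods return both their waters and arable pairs.
    """
    computed = entry.computed_area_per_kg
    primary = computed
    if entry.area_per_kg_override is not None:
        if not math.isclose(entry.area_per_kg_override, computed, abs_tol=0.005):
            logger.warning(
                "%s: using printed area-per-kg %.4g; omega/phi gives %.4g",
                entry.food_id,
                entry.area_per_kg_override,
                computed,
            )
        primary = entry.area_per_kg_override

    pairs = [(entry.land_type, primary)]
    if entry.second_land_type is not None:
        second = (
            entry.second_area_per_kg
            if entry.second_area_per_kg is not None
            else computed
        )
        pairs.append((entry.second_land_type, second))
    return pairs


@dataclass
class ConsumptionProfile:
    """Per-capita annual consumption, kg/yr per food item.

    A total ``fruits`` row, if present, is split into fresh and dried
    fruit by ``fruit_fresh_fraction`` before conversion.
    """

    consumption: Mapping[str, float]
    fruit_fresh_fraction: float = DEFAULT_FRUIT_FRESH_FRACTION

    def __post_init__(self) -> None:
        if not 0.0 <= self.fruit_fresh_fraction <= 1.0:
            raise ValidationError(
                f"fruit_fresh_fraction must be in [0, 1], got "
                f"{self.fruit_fresh_fraction}"
            )
        for food_id, kg in self.consumption.items():
            if kg < 0:
                raise ValidationError(
                    f"negative consumption for {food_id!r}: {kg}"
                )

    def resolved(self) -> dict[str, float]:
        """Consumption with the fruit total split into fresh/dried ids."""
        out: dict[str, float] = {}
        for food_id, kg in self.consumption.items():
            if food_id == FRUIT_TOTAL_ID:
                f = self.fruit_fresh_fraction
                out[FRUIT_FRESH_ID] = out.get(FRUIT_FRESH_ID, 0.0) + kg * f
                out[FRUIT_DRIED_ID] = out.get(FRUIT_DRIED_ID, 0.0) + kg * (1 - f)
            else:
                out[food_id] = out.get(food_id, 0.0) + kg
        return out


@dataclass(frozen=True)
class PerCapitaDemand:
    """Per-capita standing land-area demand, m²/capita/yr, by land type."""

    demand_m2: Mapping[LandType, float] = field(
        default_factory=lambda: {lt: 0.0 for lt in LandType}
    )

    def __getitem__(self, land_type: LandType) -> float:
        return self.demand_m2.get(land_type, 0.0)

    @property
    def total_m2(self) -> float:
        return sum(self.demand_m2.values())

    def scaled(self, alpha: float) -> "PerCapitaDemand":
        return PerCapitaDemand({lt: alpha * v for lt, v in self.demand_m2.items()})


class ConversionTable:
    """Lookup of :class:`ConversionEntry` by food id."""

    def __init__(self, entries: Iterable[ConversionEntry]):
        self._entries = {e.food_id: e for e in entries}

    def __getitem__(self, food_id: str) -> ConversionEntry:
        try:
            return self._entries[food_id]
        except KeyError:
            raise LookupError_(
                f"no conversion entry for food {food_id!r}"
            ) from None

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)


def per_capita_demand(
    profile: ConsumptionProfile, table: ConversionTable
) -> PerCapitaDemand:
    """Aggregate FC × area-per-kg over all consumed foods, by land type.

    Aquatic consumption contributes to both the waters and arable totals
    through its two coefficients.
    """
    totals: dict[LandType, float] = {lt: 0.0 for lt in LandType}
    for food_id, kg in profile.resolved().items():
        entry = table[food_id]
        for land_type, coeff in area_per_kg(entry):
            totals[land_type] += kg * coeff
    return PerCapitaDemand(totals)


# ---------------------------------------------------------------------------
# CSV I/O


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def load_conversion_table(path: str | Path) -> ConversionTable:
    """Read a conversion table CSV.

    Columns: ``food_id, category, omega, phi, land_type,
    area_per_kg_override, second_land_type, second_area_per_kg`` (the last
    four may be blank).
    """
    df = pd.read_csv(path, dtype={"food_id": str, "category": str})
    entries = []
    for row in df.itertuples(index=False):
        second_lt = getattr(row, "second_land_type", None)
        if isinstance(second_lt, float) and math.isnan(second_lt):
            second_lt = None
        entries.append(
            ConversionEntry(
                food_id=row.food_id,
                category=row.category,
                omega=float(row.omega),
                phi=_opt_float(getattr(row, "phi", None)),
                land_type=LandType(row.land_type),
                area_per_kg_override=_opt_float(
                    getattr(row, "area_per_kg_override", None)
                ),
                second_land_type=LandType(second_lt) if second_lt else None,
                second_area_per_kg=_opt_float(
                    getattr(row, "second_area_per_kg", None)
                ),
            )
        )
    return ConversionTable(entries)


def load_consumption(
    path: str | Path,
    fruit_fresh_fraction: float = DEFAULT_FRUIT_FRESH_FRACTION,
) -> ConsumptionProfile:
    """Read a consumption CSV with columns ``food_id, kg_per_capita_year``."""
    df = pd.read_csv(path, dtype={"food_id": str})
    return ConsumptionProfile(
        dict(zip(df["food_id"], df["kg_per_capita_year"].astype(float))),
        fruit_fresh_fraction=fruit_fresh_fraction,
    )


def packaged_data(name: str):
    """Path-like handle on a CSV shipped inside the package."""
    return resources.files("foodshed.data").joinpath(name)


def load_default_conversion_table() -> ConversionTable:
    """The shipped conversion table of printed coefficients."""
    with resources.as_file(packaged_data("conversion_table.csv")) as p:
        return load_conversion_table(p)
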