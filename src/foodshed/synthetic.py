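"""Synthetic study regions: land cover, city polygons, diet tables.

Everything the pipeline consumes can be generated here under a single
seed, so the full foodshed analysis is testable end-to-end without any
external download. The generator emulates the structure of a megacity
region: a clustered multi-class land-cover raster, a Voronoi partition
of the extent into prefecture-like city polygons with populations, and a
consumption/conversion table pair.

Defaults mirror a Pearl-River-Delta-like region: a ~235 km square extent
(≈55,000 km²), nine cities with populations between 2.4 and 19 million,
and a land mix in which arable land is scarce relative to demand.
Land-cover fields are produced by rank-thresholding smoothed Gaussian
noise, which hits the requested class fractions exactly (to one cell)
while giving spatially clustered patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .demand import DEFAULT_POPULATION_UNIT, GeoUnit
from .errors import ValidationError
from .footprint import (
    ConsumptionProfile,
    ConversionEntry,
    ConversionTable,
    LandType,
    load_consumption,
    load_conversion_table,
)
from .geodata import CLASS_CODES, NONE_CODE, LandCoverGrid, write_ascii_grid

#: class assignment order for the rank thresholding (stable, documented)
_CLASS_ORDER = ["arable", "horticultural", "waters", "other"]

_PRD_LIKE_FRACTIONS = {
    "arable": 0.25,
    "horticultural": 0.08,
    "waters": 0.10,
    "other": 0.57,
}


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic study region.

    ``class_fractions`` maps ``arable``, ``horticultural``, ``waters``
    and ``other`` to shares summing to 1. ``clustering_length_km`` is the
    spatial correlation scale of the land-cover field (0 = independent
    cells). ``population_range`` is in persons.
    """

    extent_km: float = 235.0
    cell_size_m: float = 1000.0
    class_fractions: dict = dc_field(
        default_factory=lambda: dict(_PRD_LIKE_FRACTIONS)
    )
    clustering_length_km: float = 5.0
    n_cities: int = 9
    population_range: tuple[float, float] = (2.4e6, 1.9e7)
    profile_preset: str = "prd_like"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_km <= 0 or self.cell_size_m <= 0:
            raise ValidationError("extent and cell size must be positive")
        fr = self.class_fractions
        unknown = set(fr) - set(_CLASS_ORDER)
        if unknown:
            raise ValidationError(f"unknown class fraction keys: {unknown}")
        if any(not 0 <= v <= 1 for v in fr.values()):
            raise ValidationError("class fractions must be in [0, 1]")
        if abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValidationError(
                f"class fractions must sum to 1, got {sum(fr.values())}"
            )
        lo, hi = self.population_range
        if lo < 0 or hi < lo:
            raise ValidationError("population_range must satisfy 0 <= lo <= hi")

    @property
    def n_cells_side(self) -> int:
        return int(round(self.extent_km * 1000.0 / self.cell_size_m))


def generate_landcover(scn: SyntheticScenario) -> LandCoverGrid:
    """Clustered multi-class raster hitting the requested fractions.

    A Gaussian random field is smoothed at the clustering length and its
    cells are assigned to classes in rank order, so empirical fractions
    match the request to within one cell regardless of grid size.
    """
    n = scn.n_cells_side
    rng = np.random.default_rng(scn.seed)
    fld = rng.standard_normal((n, n))
    if scn.clustering_length_km > 0:
        sigma = scn.clustering_length_km * 1000.0 / scn.cell_size_m
        fld = gaussian_filter(fld, sigma=sigma)
    order = np.argsort(fld.ravel(), kind="stable")

    codes = np.empty(n * n, dtype=np.int8)
    start = 0
    cum = 0.0
    for name in _CLASS_ORDER:
        cum += scn.class_fractions.get(name, 0.0)
        stop = n * n if name == _CLASS_ORDER[-1] else int(round(cum * n * n))
        code = NONE_CODE if name == "other" else CLASS_CODES[LandType(name)]
        codes[order[start:stop]] = code
        start = stop
    return LandCoverGrid(
        codes.reshape(n, n),
        cell_size_m=scn.cell_size_m,
        x_origin=0.0,
        y_origin=n * scn.cell_size_m,
        crs_tag="synthetic-metric",
    )


def generate_cities(scn: SyntheticScenario) -> list[GeoUnit]:
    """Voronoi partition of the extent into city polygons with populations.

    Seed points are uniform in the extent; the resulting polygons tile
    the extent without overlap. Populations are uniform draws from
    ``population_range``.
    """
    if scn.n_cities < 1:
        raise ValidationError("n_cities must be >= 1")
    n_cells = scn.n_cells_side**2
    if scn.n_cities > max(1, n_cells // 4):
        raise ValidationError(
            f"{scn.n_cities} cities exceed what a {scn.n_cells_side}^2-cell "
            "extent supports"
        )
    rng = np.random.default_rng(scn.seed + 1)
    side_m = scn.extent_km * 1000.0
    extent = box(0.0, 0.0, side_m, side_m)
    pops = rng.uniform(*scn.population_range, size=scn.n_cities)

    if scn.n_cities == 1:
        return [GeoUnit("city01", "City 01", float(pops[0]), extent)]

    pts = [
        Point(x, y)
        for x, y in zip(
            rng.uniform(0, side_m, scn.n_cities),
            rng.uniform(0, side_m, scn.n_cities),
        )
    ]
    cells = voronoi_diagram(MultiPoint(pts), envelope=extent)
    units: list[GeoUnit] = []
    polys = [c.intersection(extent) for c in cells.geoms]
    for i, pt in enumerate(pts):
        poly = next(p for p in polys if p.covers(pt))
        units.append(
            GeoUnit(f"city{i + 1:02d}", f"City {i + 1:02d}", float(pops[i]), poly)
        )
    return units


def _toy_conversion_table() -> ConversionTable:
    return ConversionTable(
        [
            ConversionEntry("cereals", "crop", 1.0, LandType.ARABLE),
            ConversionEntry("fruit_fresh", "fruit_fresh", 1.0, LandType.HORTICULTURAL),
            ConversionEntry("fruit_dried", "fruit_dried", 1.0, LandType.HORTICULTURAL),
            ConversionEntry(
                "aquatic",
                "aquatic",
                1.0,
                LandType.WATERS,
                phi=1.0,
                area_per_kg_override=1.0,
                second_land_type=LandType.ARABLE,
                second_area_per_kg=1.0,
            ),
        ]
    )


def generate_consumption(
    preset: str = "prd_like",
) -> tuple[ConsumptionProfile, ConversionTable]:
    """A consumption profile and its matching conversion table.

    ``prd_like`` ships a 13-item basket representative of a south-China
    megacity diet together with the printed conversion coefficients; its
    implied per-capita arable demand lands near 917 m²/capita.
    ``uniform_toy`` is a 3-item unit-coefficient profile convenient for
    analytic checks (100 kg cereals → exactly 100 m² arable, etc.).
    """
    if preset == "prd_like":
        with resources.as_file(
            resources.files("foodshed.data").joinpath("conversion_table.csv")
        ) as p:
            table = load_conversion_table(p)
        with resources.as_file(
            resources.files("foodshed.data").joinpath(
                "prd_consumption_synthetic.csv"
            )
        ) as p:
            profile = load_consumption(p)
        return profile, table
    if preset == "uniform_toy":
        profile = ConsumptionProfile(
            {"cereals": 100.0, "fruits": 10.0, "aquatic": 10.0},
            fruit_fresh_fraction=0.5,
        )
        return profile, _toy_conversion_table()
    raise ValidationError(f"unknown consumption preset {preset!r}")


def write_scenario(scn: SyntheticScenario, outdir: str | Path) -> dict[str, Path]:
    """Materialize a scenario as pipeline-ready files plus a manifest.

    Writes the land-cover ASCII grid, boundary GeoJSON, population and
    consumption/conversion CSVs, and a ``manifest.yaml`` recording the
    seed and parameters for provenance. Returns the path of each output.
    """
    from .geodata import write_boundaries_geojson  # local to avoid cycle noise
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    grid = generate_landcover(scn)
    units = generate_cities(scn)
    profile, table = generate_consumption(scn.profile_preset)

    paths = {
        "landcover": outdir / "landcover.asc",
        "boundaries": outdir / "boundaries.geojson",
        "population": outdir / "population.csv",
        "consumption": outdir / "consumption.csv",
        "conversion": outdir / "conversion.csv",
        "manifest": outdir / "manifest.yaml",
    }
    write_ascii_grid(grid, paths["landcover"])
    write_boundaries_geojson(units, paths["boundaries"])
    pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in units],
            "name": [u.name for u in units],
            # populations stored in the same 10^4-person unit the regional
            # fixture uses, re-inflated by population_unit at load time
            "population": [u.population / DEFAULT_POPULATION_UNIT for u in units],
        }
    ).to_csv(paths["population"], index=False)
    pd.DataFrame(
        {
            "food_id": list(profile.consumption),
            "kg_per_capita_year": list(profile.consumption.values()),
        }
    ).to_csv(paths["consumption"], index=False)
    _conversion_to_csv(table, paths["conversion"])
    manifest = {
        "seed": scn.seed,
        "extent_km": scn.extent_km,
        "cell_size_m": scn.cell_size_m,
        "class_fractions": dict(scn.class_fractions),
        "clustering_length_km": scn.clustering_length_km,
        "n_cities": scn.n_cities,
        "population_range": list(scn.population_range),
        "profile_preset": scn.profile_preset,
        "population_unit": DEFAULT_POPULATION_UNIT,
        "fruit_fresh_fraction": profile.fruit_fresh_fraction,
    }
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=False))
    return paths


def _conversion_to_csv(table: ConversionTable, path: Path) -> None:
    import pandas as pd

    rows = []
    for e in table:
        rows.append(
            {
                "food_id": e.food_id,
                "category": e.category,
                "omega": e.omega,
                "phi": e.phi,
                "land_type": e.land_type.value,
                "area_per_kg_override": e.area_per_kg_override,
                "second_land_type": (
                    e.second_land_type.value if e.second_land_type else None
                ),
                "second_area_per_kg": e.second_area_per_kg,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
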