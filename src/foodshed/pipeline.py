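"""End-to-end pipeline: consumption → demand → foodsheds → report.

The four stages are (1) land-type footprint of the diet, (2) scaling to
city and regional totals, (3) available-area accounting on the land-cover
grid, and (4) radius delineation with self-sufficiency rates. The
regional run uses the union of the city boundaries and the summed
population. Output is a results CSV (one row per unit, three land-type
column blocks), a GeoJSON of foodshed circles, and a YAML run log of all
resolved parameters. A run is a pure function of its inputs and
configuration: re-running a config reproduces the outputs bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml
from shapely.ops import unary_union

from .delineation import FoodshedResult, SearchConfig, delineate_unit
from .demand import DEFAULT_POPULATION_UNIT, DemandTable, GeoUnit, load_populations
from .errors import PipelineError, ValidationError
from .footprint import (
    DEFAULT_FRUIT_FRESH_FRACTION,
    LandType,
    load_consumption,
    load_conversion_table,
    per_capita_demand,
)
from .geodata import (
    circle_polygon,
    read_ascii_grid,
    read_boundaries_geojson,
)

logger = logging.getLogger(__name__)

REGION_ID = "region"


@dataclass
class RunConfig:
    """Resolved inputs and parameters of one pipeline run."""

    landcover: Path
    boundaries: Path
    population: Path
    consumption: Path
    conversion: Path
    output_dir: Path
    population_unit: float = DEFAULT_POPULATION_UNIT
    fruit_fresh_fraction: float = DEFAULT_FRUIT_FRESH_FRACTION
    search: SearchConfig = dc_field(default_factory=SearchConfig)
    region_name: str = "Region"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for attr in ("landcover", "boundaries", "population", "consumption",
                     "conversion", "output_dir"):
            setattr(self, attr, Path(getattr(self, attr)))
        for attr in ("landcover", "boundaries", "population", "consumption",
                     "conversion"):
            p: Path = getattr(self, attr)
            if not p.exists():
                raise ValidationError(f"{attr} file does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        search_keys = (
            "initial_radius_km", "step_km", "threshold_km2", "max_radius_km",
            "use_representative_point",
        )
        search = SearchConfig(**{k: doc.pop(k) for k in search_keys if k in doc})
        base = Path(path).parent
        for key in ("landcover", "boundaries", "population", "consumption",
                    "conversion", "output_dir"):
            if key in doc and not Path(doc[key]).is_absolute():
                doc[key] = base / doc[key]
        return cls(search=search, **doc)


@dataclass
class ResultsBundle:
    """Everything one run computes, plus where it was written."""

    per_capita_m2: dict[LandType, float]
    units: list[GeoUnit]
    demand_table: DemandTable
    results: list[FoodshedResult]  # cities then region, three rows per unit
    output_files: dict[str, Path]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(cfg: RunConfig) -> ResultsBundle:
    """Execute all four stages and write the report files.

    On any stage failure the partially written outputs are removed and a
    :class:`PipelineError` naming the stage propagates.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        with _stage("load-inputs"):
            grid = read_ascii_grid(cfg.landcover)
            boundaries = read_boundaries_geojson(cfg.boundaries)
            units = load_populations(cfg.population, cfg.population_unit)
            for u in units:
                if u.unit_id not in boundaries:
                    raise ValidationError(f"no boundary for unit {u.unit_id!r}")
                u.boundary = boundaries[u.unit_id]
            table = load_conversion_table(cfg.conversion)
            profile = load_consumption(cfg.consumption, cfg.fruit_fresh_fraction)

        with _stage("footprint"):
            pc = per_capita_demand(profile, table)

        with _stage("demand"):
            demand = DemandTable.from_units(pc, units)
            region_unit = GeoUnit(
                REGION_ID,
                cfg.region_name,
                sum(u.population for u in units),
                unary_union([u.boundary for u in units]),
            )
            demand = demand.with_region_row(
                REGION_ID, [u.unit_id for u in units]
            )

        with _stage("delineation"):
            results: list[FoodshedResult] = []
            for u in [*units, region_unit]:
                for lt in LandType:
                    results.append(
                        delineate_unit(
                            u, demand.demand(u.unit_id, lt), grid, lt, cfg.search
                        )
                    )

        with _stage("report"):
            files = _write_reports(cfg, units, region_unit, results)
            written.extend(files.values())

    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise

    return ResultsBundle(
        per_capita_m2={lt: pc[lt] for lt in LandType},
        units=[*units, region_unit],
        demand_table=demand,
        results=results,
        output_files=files,
    )


def results_frame(
    units: list[GeoUnit],
    results: list[FoodshedResult],
    population_unit: float = DEFAULT_POPULATION_UNIT,
) -> pd.DataFrame:
    """Tabulate results in the one-row-per-unit report layout.

    km², km and % are rounded to 2 decimals (the reporting precision);
    populations are reported back in the input unit.
    """
    by_unit: dict[str, dict] = {}
    pops = {u.unit_id: u for u in units}
    for r in results:
        row = by_unit.setdefault(
            r.unit_id,
            {
                "unit_id": r.unit_id,
                "name": pops[r.unit_id].name,
                "population": round(pops[r.unit_id].population / population_unit, 2),
            },
        )
        ssr = r.self_sufficiency_pct
        row[f"{r.land_type.value}_ssr_pct"] = (
            round(ssr, 2) if ssr is not None else float("nan")
        )
        row[f"{r.land_type.value}_demand_km2"] = round(r.demand_km2, 2)
        row[f"{r.land_type.value}_radius_km"] = round(r.radius_km, 2)
        row[f"{r.land_type.value}_met"] = r.met
        row[f"{r.land_type.value}_in_boundary"] = r.restricted_to_boundary
    return pd.DataFrame([by_unit[u.unit_id] for u in units])


def _write_reports(
    cfg: RunConfig,
    units: list[GeoUnit],
    region_unit: GeoUnit,
    results: list[FoodshedResult],
) -> dict[str, Path]:
    out = cfg.output_dir
    files = {
        "results_csv": out / "results.csv",
        "foodsheds_geojson": out / "foodsheds.geojson",
        "run_log": out / "run_log.yaml",
    }
    frame = results_frame([*units, region_unit], results, cfg.population_unit)
    frame.to_csv(files["results_csv"], index=False)

    centers = {u.unit_id: u.centroid for u in [*units, region_unit]}
    features = []
    for r in results:
        poly = circle_polygon(centers[r.unit_id], r.radius_km)
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "unit_id": r.unit_id,
                    "land_type": r.land_type.value,
                    "radius_km": round(r.radius_km, 2),
                    "demand_km2": round(r.demand_km2, 2),
                    "met": r.met,
                },
                "geometry": json.loads(json.dumps(poly.__geo_interface__)),
            }
        )
    files["foodsheds_geojson"].write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )

    log = {
        "inputs": {
            k: str(getattr(cfg, k))
            for k in ("landcover", "boundaries", "population", "consumption",
                      "conversion")
        },
        "population_unit": cfg.population_unit,
        "fruit_fresh_fraction": cfg.fruit_fresh_fraction,
        "search": {
            "initial_radius_km": cfg.search.initial_radius_km,
            "step_km": cfg.search.step_km,
            "threshold_km2": cfg.search.threshold_km2,
            "max_radius_km": cfg.search.max_radius_km,
        },
    }
    files["run_log"].write_text(yaml.safe_dump(log, sort_keys=False))
    return files


# ---------------------------------------------------------------------------
# Consistency checks


def consistency_report(
    frame: pd.DataFrame,
    region_id: str = REGION_ID,
    additivity_tol_km2: float = 0.02,
    rate_rtol: float = 1e-2,
) -> pd.DataFrame:
    """Cross-checks on a results table in the report CSV layout.

    Verifies, per land type, that the region demand equals the sum of
    the city demands (within ``additivity_tol_km2`` accumulated
    rounding), that the three land-type shares of regional demand sum to
    100%, and that demand per capita is constant across cities (the same
    consumption profile drives every city; ``rate_rtol`` absorbs the
    2-decimal rounding of reported values). Returns a pass/fail table.
    """
    frame = frame.set_index("unit_id") if "unit_id" in frame.columns else frame
    if region_id not in frame.index:
        raise ValidationError(f"no region row {region_id!r} in results")
    cities = frame.drop(index=region_id)
    region = frame.loc[region_id]
    checks = []
    for lt in LandType:
        col = f"{lt.value}_demand_km2"
        gap = abs(cities[col].sum() - region[col])
        checks.append(
            {
                "check": "region_additivity",
                "land_type": lt.value,
                "passed": bool(gap <= additivity_tol_km2 + 1e-9),
                "detail": f"|sum(cities) - region| = {gap:.4f} km2",
            }
        )
    total = sum(region[f"{lt.value}_demand_km2"] for lt in LandType)
    share_sum = sum(
        100.0 * region[f"{lt.value}_demand_km2"] / total for lt in LandType
    )
    checks.append(
        {
            "check": "shares_sum_to_100",
            "land_type": "all",
            "passed": bool(abs(share_sum - 100.0) <= 1e-9),
            "detail": f"sum of shares = {share_sum:.9f}%",
        }
    )
    for lt in LandType:
        col = f"{lt.value}_demand_km2"
        rates = cities[col] / cities["population"]
        spread = float(rates.max() - rates.min()) / float(rates.mean())
        checks.append(
            {
                "check": "per_capita_rate_constant",
                "land_type": lt.value,
                "passed": bool(spread <= rate_rtol),
                "detail": f"relative spread of demand/population = {spread:.2e}",
            }
        )
    return pd.DataFrame(checks)
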