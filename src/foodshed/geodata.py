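"""Land-cover grids, reclassification and area accounting.

A :class:`LandCoverGrid` is a regular raster in metric projected
coordinates whose cells carry one of the three agricultural land types
(arable, horticultural, waters) or none. Areas are counted with the
cell-center rule: a cell belongs to a polygon or circle iff its center
does. This makes every area query deterministic and resolution-controlled
(the error vanishes as the cell size shrinks) at the cost of ignoring
fractional cell coverage.

Raster I/O uses the ESRI ASCII grid format (plain text, one integer code
per cell); vector I/O uses GeoJSON.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import shapely
from shapely.geometry import Point, Polygon, box, mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import ValidationError
from .footprint import LandType

logger = logging.getLogger(__name__)

#: canonical integer codes of the reclassified grid
NONE_CODE = 0
CLASS_CODES: dict[LandType, int] = {
    LandType.ARABLE: 1,
    LandType.HORTICULTURAL: 2,
    LandType.WATERS: 3,
}

_GEOGRAPHIC_HINTS = ("4326", "wgs84", "wgs 84", "crs84", "degree", "longlat")


def _check_projected(crs_tag: str) -> None:
    low = crs_tag.lower()
    if any(h in low for h in _GEOGRAPHIC_HINTS):
        raise ValidationError(
            f"crs_tag {crs_tag!r} looks geographic (degrees). This package "
            "requires metre-based projected coordinates; reproject the "
            "inputs (e.g. to a UTM zone) before loading them."
        )


@dataclass
class LandCoverGrid:
    """Reclassified land-cover raster.

    ``classes`` holds canonical codes (0 = none, 1 = arable,
    2 = horticultural, 3 = waters); row 0 is the northern edge.
    ``x_origin``/``y_origin`` are the coordinates (m) of the grid's
    top-left corner; the center of cell (i, j) sits at
    ``(x_origin + (j + 0.5) h, y_origin - (i + 0.5) h)`` for cell size h.
    """

    classes: np.ndarray
    cell_size_m: float
    x_origin: float = 0.0
    y_origin: float | None = None
    crs_tag: str = "local-metric"

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 2:
            raise ValidationError("class grid must be 2-D")
        if not self.cell_size_m > 0:
            raise ValidationError("cell_size_m must be > 0")
        _check_projected(self.crs_tag)
        if self.y_origin is None:
            # default: y origin at the top so the grid spans [0, height]
            self.y_origin = self.classes.shape[0] * self.cell_size_m

    @property
    def shape(self) -> tuple[int, int]:
        return self.classes.shape  # type: ignore[return-value]

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_m**2 / 1e6

    @property
    def extent(self) -> Polygon:
        """Bounding box of the grid in map coordinates."""
        nrows, ncols = self.shape
        h = self.cell_size_m
        return box(
            self.x_origin,
            self.y_origin - nrows * h,
            self.x_origin + ncols * h,
            self.y_origin,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates (m) of every cell center, row-major."""
        nrows, ncols = self.shape
        h = self.cell_size_m
        xs = self.x_origin + (np.arange(ncols) + 0.5) * h
        ys = self.y_origin - (np.arange(nrows) + 0.5) * h
        xx, yy = np.meshgrid(xs, ys)
        return xx.ravel(), yy.ravel()

    def class_mask(self, land_type: LandType) -> np.ndarray:
        return self.classes == CLASS_CODES[land_type]

    def total_area_km2(self, land_type: LandType) -> float:
        return int(self.class_mask(land_type).sum()) * self.cell_area_km2

    def class_fractions(self) -> dict[LandType, float]:
        n = self.classes.size
        return {
            lt: int(self.class_mask(lt).sum()) / n for lt in LandType
        }


def reclassify(
    raw: np.ndarray,
    class_map: Mapping[int, LandType | str | None],
    *,
    cell_size_m: float,
    x_origin: float = 0.0,
    y_origin: float | None = None,
    crs_tag: str = "local-metric",
    unmapped: str = "error",
) -> LandCoverGrid:
    """Map raw integer land-use codes onto the three agricultural classes.

    ``class_map`` sends each raw code to a :class:`LandType`, its string
    value, or None (= no agricultural class). Codes absent from the map
    raise unless ``unmapped="none"`` declares them non-agricultural.
    """
    raw = np.asarray(raw)
    present = np.unique(raw)
    canonical = {}
    for code, target in class_map.items():
        if target is None or target == "none":
            canonical[int(code)] = NONE_CODE
        else:
            canonical[int(code)] = CLASS_CODES[LandType(target)]
    missing = [int(c) for c in present if int(c) not in canonical]
    if missing:
        if unmapped == "none":
            for c in missing:
                canonical[c] = NONE_CODE
        else:
            raise ValidationError(
                f"raw codes {missing} have no class mapping; pass "
                "unmapped='none' to treat them as non-agricultural"
            )
    out = np.zeros(raw.shape, dtype=np.int8)
    for code, canon in canonical.items():
        out[raw == code] = canon
    return LandCoverGrid(
        out,
        cell_size_m=cell_size_m,
        x_origin=x_origin,
        y_origin=y_origin,
        crs_tag=crs_tag,
    )


def _eligible_centers(
    grid: LandCoverGrid, land_type: LandType, mask: BaseGeometry | None
) -> tuple[np.ndarray, np.ndarray]:
    """Map coordinates of cell centers of ``land_type``, optionally
    restricted to centers inside ``mask``."""
    sel = grid.class_mask(land_type).ravel()
    xs, ys = grid.cell_centers()
    xs, ys = xs[sel], ys[sel]
    if mask is not None and len(xs):
        shapely.prepare(mask)
        inside = shapely.contains_xy(mask, xs, ys)
        xs, ys = xs[inside], ys[inside]
    return xs, ys


def area_within_polygon(
    grid: LandCoverGrid, polygon: BaseGeometry, land_type: LandType
) -> float:
    """km² of ``land_type`` cells whose center lies inside ``polygon``."""
    if not polygon.intersects(grid.extent):
        logger.warning("polygon is disjoint from the grid extent; area = 0")
        return 0.0
    xs, ys = _eligible_centers(grid, land_type, polygon)
    return len(xs) * grid.cell_area_km2


def area_within_circle(
    grid: LandCoverGrid,
    center: Point | tuple[float, float],
    radius_km: float,
    land_type: LandType,
    mask: BaseGeometry | None = None,
) -> float:
    """km² of ``land_type`` cells within ``radius_km`` of ``center``.

    When ``mask`` is given, only cells inside it are eligible (the
    in-boundary branch of the delineation).
    """
    if radius_km < 0:
        raise ValidationError("radius_km must be >= 0")
    if radius_km == 0:
        return 0.0  # a degenerate circle encloses no area
    cx, cy = (center.x, center.y) if isinstance(center, Point) else center
    xs, ys = _eligible_centers(grid, land_type, mask)
    if not len(xs):
        return 0.0
    d_km = np.hypot(xs - cx, ys - cy) / 1000.0
    return int((d_km <= radius_km).sum()) * grid.cell_area_km2


@dataclass
class DistanceIndex:
    """Sorted cell-center distances from a fixed center for one land type.

    Supports O(log n) radius→area and area→radius queries that agree
    exactly with :func:`area_within_circle` for the same center, class
    and mask (both count centers at distance ≤ r, computed identically).
    """

    distances_km: np.ndarray  # sorted, ascending
    cell_area_km2: float

    @property
    def n_cells(self) -> int:
        return len(self.distances_km)

    @property
    def total_area_km2(self) -> float:
        return self.n_cells * self.cell_area_km2

    def area_at(self, radius_km: float) -> float:
        """Accumulated class area (km²) within ``radius_km``."""
        if radius_km == 0:
            return 0.0  # degenerate circle, mirrors area_within_circle
        count = int(np.searchsorted(self.distances_km, radius_km, side="right"))
        return count * self.cell_area_km2

    def radius_for_area(self, target_km2: float) -> float | None:
        """Smallest cell-center distance at which the accumulated area
        reaches ``target_km2``; None if the class cannot supply it."""
        if target_km2 <= 0:
            return 0.0
        k = int(math.ceil(target_km2 / self.cell_area_km2 - 1e-12))
        if k > self.n_cells:
            return None
        return float(self.distances_km[k - 1])


def build_distance_index(
    grid: LandCoverGrid,
    center: Point | tuple[float, float],
    land_type: LandType,
    mask: BaseGeometry | None = None,
) -> DistanceIndex:
    """Precompute the cumulative area-vs-distance curve around ``center``."""
    cx, cy = (center.x, center.y) if isinstance(center, Point) else center
    if not (math.isfinite(cx) and math.isfinite(cy)):
        raise ValidationError("center coordinates must be finite")
    xs, ys = _eligible_centers(grid, land_type, mask)
    d_km = np.sort(np.hypot(xs - cx, ys - cy) / 1000.0)
    return DistanceIndex(d_km, grid.cell_area_km2)


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text raster interchange)


def write_ascii_grid(grid: LandCoverGrid, path: str | Path) -> None:
    """Write the class raster as an ESRI ASCII grid (.asc).

    The CRS tag is stored in a ``<name>.crs.txt`` sidecar since the
    format itself carries no reference-system field.
    """
    path = Path(path)
    nrows, ncols = grid.shape
    yll = grid.y_origin - nrows * grid.cell_size_m
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.x_origin:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {grid.cell_size_m:.6f}\n")
        fh.write("NODATA_value -9999\n")
        np.savetxt(fh, grid.classes, fmt="%d")
    path.with_suffix(".crs.txt").write_text(grid.crs_tag + "\n")


def read_ascii_grid(path: str | Path, crs_tag: str | None = None) -> LandCoverGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, dtype=np.int8)
    data = np.atleast_2d(data)
    if crs_tag is None:
        sidecar = path.with_suffix(".crs.txt")
        crs_tag = sidecar.read_text().strip() if sidecar.exists() else "local-metric"
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    return LandCoverGrid(
        data,
        cell_size_m=cell,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cell,
        crs_tag=crs_tag,
    )


# ---------------------------------------------------------------------------
# GeoJSON I/O


def write_boundaries_geojson(
    units: Mapping[str, BaseGeometry] | list, path: str | Path, names=None
) -> None:
    """Write unit boundaries as a GeoJSON FeatureCollection.

    Accepts either a mapping unit_id → geometry or a list of objects with
    ``unit_id``, ``name`` and ``boundary`` attributes (e.g. GeoUnit).
    """
    features = []
    if isinstance(units, Mapping):
        items = [(uid, (names or {}).get(uid, uid), geom) for uid, geom in units.items()]
    else:
        items = [(u.unit_id, u.name, u.boundary) for u in units]
    for uid, name, geom in items:
        features.append(
            {
                "type": "Feature",
                "properties": {"unit_id": uid, "name": name},
                "geometry": mapping(geom),
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def read_boundaries_geojson(path: str | Path) -> dict[str, BaseGeometry]:
    """Read a FeatureCollection back into a unit_id → geometry mapping."""
    doc = json.loads(Path(path).read_text())
    out: dict[str, BaseGeometry] = {}
    for feat in doc["features"]:
        uid = feat.get("properties", {}).get("unit_id")
        if uid is None:
            raise ValidationError("feature without a unit_id property")
        out[uid] = shape(feat["geometry"])
    return out


def circle_polygon(
    center: Point | tuple[float, float], radius_km: float, n_segments: int = 64
) -> Polygon:
    """Polygonal approximation of a foodshed circle (radius in km,
    coordinates in m)."""
    cx, cy = (center.x, center.y) if isinstance(center, Point) else center
    if radius_km <= 0:
        return Point(cx, cy).buffer(0)  # empty polygon
    theta = np.linspace(0.0, 2 * np.pi, n_segments, endpoint=False)
    r_m = radius_km * 1000.0
    return Polygon(zip(cx + r_m * np.cos(theta), cy + r_m * np.sin(theta)))
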