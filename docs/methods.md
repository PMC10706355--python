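# Methods

## Model overview

The package implements a capacity-style foodshed assessment in four
stages.

1. **Footprint.** Per-capita consumption `FC` (kg/yr) of each food is
   converted to standing agricultural area via `LD = FC·ω` for plant
   foods and `LD = FC·ω/φ` for feed-raised products, where ω (m²/kg) is
   the reciprocal of yield and φ (kg product per kg feed) the feed
   conversion rate. Demand is a standing area — the land needed for one
   year of production — not a cumulative quantity. Grassland-based
   livestock is out of scope: the model assumes animal products are
   raised on arable-grown feed, which matches intensive peri-urban
   production systems.
2. **Scaling.** `LD_total = LD · POP`, reported in km². Demand is
   homogeneous of degree 1 in population, and a region's demand is the
   exact sum of its members'.
3. **Area accounting.** Available area of each land type inside a
   boundary polygon is counted on a reclassified land-cover raster.
4. **Delineation.** The foodshed is the smallest circle centered on the
   unit's centroid whose enclosed class area meets demand; the
   self-sufficiency rate is `100 · available / demanded`.

## Conversion coefficients

The shipped table stores, per food: ω, φ (absent for plant foods), the
target land type, and an optional printed override of the area-per-kg
quotient. For pork (7.92 vs computed 7.76 m²/kg) and beef/mutton (8.35
vs 8.22) the source table's printed column disagrees slightly with ω/φ,
possibly reflecting extra feed-chain losses; the printed value is
treated as authoritative, the quotient is logged as a warning, and both
values are exposed programmatically. The aquatic waters coefficient
(1.23 m²/kg) has no ω/φ derivation and is stored as a direct printed
coefficient; the aquatic arable (feed) coefficient is the quotient
2.46/2.22 ≈ 1.11. Aquatic consumption therefore charges *both* waters
and arable totals.

Fruit consumption is given as a single total and split into fresh and
dried fractions before conversion (0.43 vs 1.72 m²/kg on horticultural
land). The split is not observable from aggregate statistics; the
default `fruit_fresh_fraction = 0.9` encodes the regional preference for
fresh fruit and is an explicit, configurable assumption.

Units of ω are fixed as m² per kg. Sanity anchor: cereals at ω = 1.59
corresponds to a yield of ~6.3 t/ha, and the implied regional per-capita
arable demand (~917 m²) back-computes consistently from the shipped
demand fixture (71,509 km² / 78.01 M persons).

## Population units

The regional population fixture stores values in units of 10⁴ persons
(the convention of the source yearbook tables); loaders take a
`population_unit` multiplier (default 1e4) and all internal arithmetic
is in persons. Report CSVs write populations back in the input unit.

## Area accounting dialect

A cell counts toward a polygon or circle iff its **center** lies inside
it (no fractional intersection). This rule is deterministic, fast, and
its error is controlled by resolution: on analytic test circles the
counted area converges to πr² as the cell size shrinks (verified at two
resolutions). Same-class cells are the patch representation; connected
components are never polygonized because the enclosed area is identical
either way. A circle of zero radius encloses no cells by convention.

Grids must be in metre-based projected coordinates. Inputs that look
geographic (degree-based CRS tags) are rejected with an instructive
error rather than silently reprojected — reprojection pipelines are out
of scope.

## Delineation

The search starts at radius 1 km and grows in 0.01 km steps until the
accumulated class area is within `threshold_km2` of the demand. The
slack threshold defaults to one grid-cell area, the finest resolvable
slack; it is configurable. Two branches:

* in-boundary class area ≥ demand → accumulation is masked to the
  boundary (the foodshed is internal; self-sufficiency ≥ 100%);
* otherwise every grid cell is eligible and the circle spills into the
  hinterland, without excluding other units' territory (each unit is
  assessed independently; competing claims on the same hinterland are a
  known limitation of the circle model, not resolved here).

Termination is guaranteed by a `max_radius_km` cap defaulting to the
grid diagonal; a search that hits the cap reports `met = false` instead
of looping forever on an insufficient grid. Zero demand returns an empty
foodshed (radius 0) rather than the 1 km floor, as the meaningful
degenerate answer; its self-sufficiency is undefined (reported as NaN,
and requesting the ratio explicitly raises).

Two equivalent implementations exist: a literal step-scan loop and a
first-crossing search on a precomputed sorted distance/cumulative-area
curve (`DistanceIndex`), with the crossing distance snapped *up* to the
0.01 km step grid and floored at the 1 km initial radius. Their exact
equivalence is property-tested on randomized grids; the index path is
the production one (it does the area accounting once instead of per
step). Both share the identical distance computation so radius↔area
queries agree exactly, not just approximately.

The circle center is the geometric centroid of the boundary polygon,
even when a concave polygon puts it outside the polygon itself; a
representative-point fallback is available behind a config flag.

## Synthetic data

The generator emulates the structure of a megacity region so the whole
pipeline is testable without external downloads:

* **Land cover** — Gaussian noise smoothed at a clustering length scale
  and rank-thresholded into classes. Rank assignment hits the requested
  class fractions exactly (to one cell) at any grid size, while the
  smoothing yields spatially clustered patches. Seeded and bit-reproducible.
* **Cities** — a Voronoi partition of the extent seeded by uniform
  points; polygons tile the extent without overlap. Populations are
  uniform draws from a configurable range.
* **Diet** — `prd_like`: a 13-item basket representative of a south-China
  urban diet, paired with the printed conversion table. The consumption
  values themselves are synthetic (the source statistics are not
  redistributable) and were chosen once to be demographically plausible
  and consistent with the regional demand fixture's implied per-capita
  rates (~917 m² arable, ~25 m² horticultural, ~42 m² waters per
  capita). `uniform_toy`: three foods with unit coefficients for
  analytic checks.

Scenario defaults describe a region of ~235 km side (≈55,000 km²), nine
cities of 2.4–19 M inhabitants, and a land mix in which arable land is
scarce relative to demand, at 1 km cell size. The generator does not
attempt realistic landscape ecology (roads, rivers, elevation, coastal
geometry) or any particular real geography, so passing tests demonstrate
the correctness of the accounting and search on controlled inputs — not
calibration against real land-cover products, which have different patch
statistics, registration error and class definitions.

## Numerical choices

* Radius search: initial radius 1.0 km, step 0.01 km; reported radii are
  step-grid values.
* Reports round km², km and % to 2 decimals; internal arithmetic is
  unrounded.
* Regional additivity on printed tables is checked to ±0.02 km²
  (accumulated rounding of 2-decimal entries); on synthetic runs the
  identity is exact before rounding.
* The area→cell-count inversion uses `ceil(target/cell_area − 1e-12)` to
  keep exact-multiple targets stable under floating point.
* Degenerate inputs: zero demand → empty foodshed; zero-radius circle →
  zero area; empty class with positive demand → `met = false`; zero
  total demand makes shares and self-sufficiency undefined (errors, not
  infinities).

## Test problem sizes

Property suites run on 50×50–200×200 grids with 0.05–0.95 class
fractions and 30 randomized scan-vs-index equivalence instances; the
analytic-radius checks use 50–100 m cells where the discretization term
(two cell widths) is small against the expected radius. These sizes were
chosen so the full suite exercises every branch in seconds while keeping
the discretization tolerance meaningful.

## Known limitations

* Food flows, wholesale-market data, food loss and waste, nutritional
  adequacy and diet optimization are out of scope.
* One consumption profile is applied to every city by default
  (per-city profiles are supported but not required).
* Overlapping foodsheds of neighboring cities are not de-conflicted;
  each unit may count the same hinterland cell.
* The circle is an idealization: coastal/sea cells inside a circle are
  simply whatever the land-cover grid says they are (typically `none` or
  `waters`), with no special handling.
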