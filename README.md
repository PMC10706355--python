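# foodshed

Foodshed delineation and food self-sufficiency assessment for cities and
megacity regions.

A *foodshed* is the territory around an urban area required to feed its
population. This package implements a capacity-style assessment: it
converts per-capita food consumption into per-land-type agricultural-area
demand, scales that demand to city and regional populations, delineates
each unit's foodshed as the smallest circle around its centroid whose
enclosed agricultural area meets demand, and reports self-sufficiency
ratios. It distinguishes three agricultural land types — **arable land**,
**horticultural landscapes** and **waters** — because a region can be
self-sufficient in one and deeply deficient in another.

Intended users: food-systems and land-use researchers, and regional
planners who want a reproducible, testable pipeline from a consumption
table and a land-cover raster to per-city foodshed radii and
self-sufficiency rates.

## Model

Per-capita land demand of food *i* (plant) or *j* (animal/aquatic):

```
LD_i = FC_i · ω_i                 (crops, fruit)
LD_j = FC_j · ω_j / φ_j           (feed-raised products)
```

where `FC` is consumption (kg/yr), `ω` the crop-to-land factor (m²/kg,
the reciprocal of yield) and `φ` the feed conversion rate (kg edible
product per kg feed). Aquatic products charge both a waters coefficient
and an arable (feed) coefficient. Totals scale linearly with population:

```
LD_total = LD · POP_total
```

The foodshed radius search starts a circle of radius 1 km at the unit's
centroid and grows it in 0.01 km steps until the enclosed class area is
within a slack threshold of the demand. If the unit's own boundary
already contains enough class area, accumulation is restricted to
in-boundary cells; otherwise the circle draws on the hinterland. The
self-sufficiency rate is `100 · available / demanded` area; ≥100% implies
theoretical export capacity.

## Worked example

```python
from foodshed import LandType, generate_consumption, per_capita_demand

profile, table = generate_consumption("prd_like")
demand = per_capita_demand(profile, table)
for lt in LandType:
    print(lt.value, round(demand[lt], 1))
```

prints

```
arable 917.9
horticultural 25.5
waters 42.3
```

i.e. one resident's annual diet ties up ~918 m² of arable land, ~25 m² of
orchard land and ~42 m² of water surface. Feeding this diet to the nine
city populations of the shipped regional fixture
(`examples/02_regional_demand.py`) gives a regional arable demand of
71,608 km² — 93.1% of total demand across the three land types — so
regional self-sufficiency hinges almost entirely on cropland.

Delineation on a synthetic grid (`examples/03_delineate_foodshed.py`): a
demand of π·2² = 12.566 km² on a fully arable 50 m grid yields a radius
of 2.01 km against the analytic 2.00 km, with self-sufficiency 795.8%
and the search restricted to the unit's own boundary.

`examples/04_full_pipeline.py` runs the whole pipeline on a generated
five-city region and prints the results table plus consistency checks
(regional additivity, share closure, per-capita rate constancy).

## Command line

```
foodshed synth --scenario scenario.yaml --out scenario_dir/
foodshed run   --config config.yaml
foodshed check --results output_dir/
```

`synth` materializes a seeded synthetic study region (land-cover grid,
Voronoi city polygons, population and diet tables, manifest); `run`
executes the pipeline and writes `results.csv`, `foodsheds.geojson` and
`run_log.yaml`; `check` re-verifies the arithmetic of a results table.

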