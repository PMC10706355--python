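"""City and regional land demand from populations.

Scales the per-capita footprint to nine city populations, sums them into
a regional total, and prints each land type's share of overall demand.
"""

from foodshed import (
    DemandTable,
    LandType,
    demand_share,
    generate_consumption,
    load_populations,
    per_capita_demand,
)
from foodshed.footprint import packaged_data
from importlib import resources

profile, table = generate_consumption("prd_like")
pc = per_capita_demand(profile, table)

with resources.as_file(packaged_data("prd_population.csv")) as p:
    units = load_populations(p, population_unit=1e4)

demand = DemandTable.from_units(pc, units).with_region_row("region")
print("Total demand (km2) per unit and land type:")
print(demand.frame.round(2).to_string())

totals = demand.aggregate_region([u.unit_id for u in units])
print("\nRegional land-type shares of total demand:")
for lt in LandType:
    print(f"  {lt.value:14s} {demand_share(totals, lt):6.2f} %")
print("\nA share this lopsided toward arable land means regional")
print("self-sufficiency hinges almost entirely on cropland supply.")
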