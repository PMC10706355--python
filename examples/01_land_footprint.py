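"""From a diet to a per-capita land footprint.

Loads the shipped conversion coefficients and a representative
south-China urban diet, and prints how much standing agricultural area
one resident's annual consumption ties up, by land type.
"""

from foodshed import LandType, generate_consumption, per_capita_demand

profile, table = generate_consumption("prd_like")
demand = per_capita_demand(profile, table)

print("Per-capita agricultural land demand (m2/capita/yr):")
for lt in LandType:
    print(f"  {lt.value:14s} {demand[lt]:8.1f}")
print(f"  {'total':14s} {demand.total_m2:8.1f}")
print()
print("Arable land dominates because cereals, oil crops and all")
print("feed-raised animal products draw on it; only fruit (horticultural)")
print("and aquatic products (waters) draw on the other two types.")
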