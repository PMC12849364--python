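"""Generate a synthetic country and inspect its structure.

Builds the default geography — a 300×360 km rectangle partitioned into 40
Voronoi regions of three urbanization classes, covered by a hexagonal
demand grid, with 100 candidate hospital sites of which 31 currently
provide the service — and prints the basic counts and per-class population
shares. These are the inputs every later stage consumes.
"""

import numpy as np

import careloc as cl

cfg = cl.SyntheticCountryConfig(seed=0)
regions, demand, hospitals = cl.generate_country(cfg)

print(f"regions: {len(regions)}  (area {regions.total_area:.0f} km²)")
print(f"demand centroids: {demand.m}  (cell area {demand.cell_area[0]:.1f} km²)")
print(f"hospitals: {hospitals.n}, current service sites: "
      f"{len(hospitals.service_ids)}")

total_pop = demand.population.sum()
print(f"total population: {total_pop/1e6:.2f} million")
for cls in ("urban", "intermediate", "rural"):
    mask = demand.urbanization == cls
    share = demand.population[mask].sum() / total_pop
    print(f"  {cls:13s} {mask.sum():5d} cells, {share:5.1%} of population")

# Each hospital coincides with a demand centroid, so zero travel time is
# attainable for the cells that host a site.
hosted = set(hospitals.demand_point_id)
print(f"cells hosting a hospital: {len(hosted)}")
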