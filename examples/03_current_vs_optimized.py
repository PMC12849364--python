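"""Current service configuration vs the optimized one.

The scaled-down analogue of the countrywide question: keeping the number
of service sites fixed, how much travel-time accessibility is gained by
reallocating the service to optimally chosen existing hospitals? Uses a
reduced country so the exact solve takes a few seconds. The weighted mean
is the population-weighted average of each cell's minutes to its nearest
open site; the threshold share is the fraction of population farther than
40 minutes from care.
"""

import careloc as cl

cfg = cl.SyntheticCountryConfig(
    country_width_km=200, country_height_km=200, n_regions=20,
    hex_spacing_km=9.0, n_hospitals=50, n_service=15, seed=0,
)
_, demand, hospitals = cl.generate_country(cfg)
T = cl.build_matrix(demand, hospitals)
W = cl.weight_matrix(T, demand)
service = hospitals.service_ids

_, cur_minutes = cl.nearest_assignment(T, service)
cur = cl.summarize(cur_minutes, demand)

sol = cl.solve_scenario(W, service, len(service), mode="liberal")
_, opt_minutes = cl.nearest_assignment(T, sol.open_sites)
opt = cl.summarize(opt_minutes, demand)

comp = cl.compare_distributions(cur_minutes, opt_minutes)

print(f"{demand.m} demand cells, {hospitals.n} candidates, "
      f"{len(service)} service sites")
print(f"weighted mean minutes : {cur.weighted_mean:6.2f} -> {opt.weighted_mean:6.2f}")
print(f"weighted median       : {cur.weighted_median:6.2f} -> {opt.weighted_median:6.2f}")
print(f"share beyond 40 min   : {cur.prop_above_threshold:6.2%} -> "
      f"{opt.prop_above_threshold:6.2%}")
print(f"Mann-Whitney U p-value for the shift in minutes: {comp.p_value:.3g}")
print("Reallocation cannot worsen the objective (the current sites are")
print("feasible for the optimizer); how much it helps depends on how far")
print("the incumbent configuration is from optimal.")
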