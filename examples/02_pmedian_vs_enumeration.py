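"""Exact p-median optimization on a tiny instance, checked by enumeration.

Three demand points A, B, C (densities 1, 2, 1) and three candidate
hospitals: the weighted travel matrix is small enough to enumerate every
possible open set, so the MILP's answer can be verified by hand. The
printed objective z is the total population-weighted travel time to the
nearest open site (person·minutes here, since cell areas are 1 km²).
"""

import numpy as np

import careloc as cl
from careloc.pmedian import ScenarioConfig, brute_force_pmedian

demand = cl.DemandSet(
    ids=["A", "B", "C"],
    xy=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
    region_id=np.array(["r"] * 3, dtype=object),
    urbanization=np.array(["intermediate"] * 3, dtype=object),
    density=np.array([1.0, 2.0, 1.0]),
    cell_area=np.ones(3),
)
t = np.array([[10.0, 20.0, 30.0], [20.0, 5.0, 25.0], [30.0, 20.0, 5.0]])
T = cl.TravelMatrix(t, list(demand.ids), ["H1", "H2", "H3"])
W = cl.weight_matrix(T, demand)

for p in (1, 2, 3):
    sol = cl.solve_scenario(W, (), p)
    oracle = brute_force_pmedian(W, ScenarioConfig(p=p))
    print(f"p={p}: MILP opens {sorted(sol.open_sites)} with z={sol.objective_z:g}; "
          f"enumeration agrees: {abs(sol.objective_z - oracle.objective_z) < 1e-9}")

# Prioritized scenario: H1 (the current service site) must stay open, and
# one extra site is added — the optimum pins H1 and adds H2 (z = 40 > 35,
# the price of keeping the incumbent).
sol = cl.solve_scenario(W, ("H1",), 2, mode="prioritized")
print(f"prioritized p=2 keeping H1: opens {sorted(sol.open_sites)}, "
      f"z={sol.objective_z:g}")
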