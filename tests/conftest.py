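"""Shared fixtures.

TOY-1 is a hand-checkable 3-demand × 3-hospital instance used across the
suite: demand A, B, C with densities (1, 2, 1) and unit cell areas, travel
minutes rows A:[10,20,30], B:[20,5,25], C:[30,20,5], hence weighted rows
A:[10,20,30], B:[40,10,50], C:[30,20,5]. All optima were verified by
exhaustive enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest

import careloc as cl


def make_demand(
    xy, density, cell_area=None, urbanization=None, region_id=None, ids=None,
    mode="planar",
) -> cl.DemandSet:
    m = len(density)
    return cl.DemandSet(
        ids=ids or [f"d{i}" for i in range(m)],
        xy=np.asarray(xy, dtype=float),
        region_id=np.array(region_id or ["r0"] * m, dtype=object),
        urbanization=np.array(urbanization or ["intermediate"] * m, dtype=object),
        density=np.asarray(density, dtype=float),
        cell_area=np.asarray(cell_area if cell_area is not None else np.ones(m)),
        mode=mode,
    )


@pytest.fixture
def toy1():
    """TOY-1 reference instance: demand, hospitals, T, W."""
    demand = make_demand(
        xy=[[0, 0], [1, 0], [2, 0]],
        density=[1.0, 2.0, 1.0],
        ids=["A", "B", "C"],
    )
    hospitals = cl.HospitalSet(
        ids=["H1", "H2", "H3"],
        xy=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
        pediatric=np.array([True, False, False]),
    )
    t = np.array([[10.0, 20.0, 30.0], [20.0, 5.0, 25.0], [30.0, 20.0, 5.0]])
    T = cl.TravelMatrix(t, list(demand.ids), list(hospitals.ids))
    W = cl.weight_matrix(T, demand)
    return {"demand": demand, "hospitals": hospitals, "T": T, "W": W}


def random_instance(seed: int, m: int = 20, n: int = 6):
    """Random planar instance with integer-valued weighted travel times
    (so oracle-vs-MILP comparisons are exact)."""
    rng = np.random.default_rng(seed)
    xy_d = rng.uniform(0, 100, (m, 2))
    xy_h = xy_d[rng.choice(m, n, replace=False)]
    t = np.linalg.norm(xy_d[:, None] - xy_h[None], axis=2)
    t = np.round(t).astype(float)
    density = rng.integers(1, 10, m).astype(float)
    demand = make_demand(xy_d, density)
    hosp_ids = [f"h{j}" for j in range(n)]
    T = cl.TravelMatrix(t, list(demand.ids), hosp_ids)
    W = cl.weight_matrix(T, demand)
    n_service = max(2, n // 3)
    service = tuple(hosp_ids[j] for j in rng.choice(n, n_service, replace=False))
    return {"demand": demand, "T": T, "W": W, "service": service,
            "hospital_ids": hosp_ids}


@pytest.fixture(scope="session")
def small_country():
    """Reduced synthetic country shared by slower integration tests."""
    cfg = cl.SyntheticCountryConfig(
        country_width_km=120.0,
        country_height_km=120.0,
        n_regions=12,
        hex_spacing_km=8.0,
        n_hospitals=30,
        n_service=10,
        seed=11,
    )
    regions, demand, hospitals = cl.generate_country(cfg)
    T = cl.build_matrix(demand, hospitals)
    W = cl.weight_matrix(T, demand)
    return {"config": cfg, "regions": regions, "demand": demand,
            "hospitals": hospitals, "T": T, "W": W}
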