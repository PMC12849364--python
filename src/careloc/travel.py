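"""Travel-time and weighted travel-time matrices.

The central objects are the m×n travel-time matrix ``t`` (rows = demand
centroids, columns = hospitals, minutes by car) and the population-weighted
matrix ``w`` with entries ``w[c,h] = p_c · t[c,h]`` where ``p_c`` is the
demand point's population density. The weighted matrix supplies the
coefficients of the p-median objective; the plain matrix supplies the
minutes reported by the accessibility metrics.

In synthetic mode travel time comes from a road-like model: straight-line
distance inflated by a detour factor and divided by an average driving
speed. For real geographies the same matrix contract can be filled by an
external matrix-routing service through :class:`RoutingAdapter`, which
caches results to CSV and validates them; the rest of the pipeline treats
the source as opaque.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .demand import DemandSet
from .errors import ValidationError
from .hospitals import HospitalSet

EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class SyntheticTravelParams:
    """Road-like travel model: ``minutes = 60 · detour · dist_km / speed``.

    speed_kmh : average door-to-door car speed; 70 km/h is a realistic
        mixed highway/rural figure.
    detour_factor : ratio of road distance to straight-line distance;
        1.3 approximates road-network circuity.
    """

    speed_kmh: float = 70.0
    detour_factor: float = 1.3

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0:
            raise ValidationError("speed_kmh must be > 0")
        if self.detour_factor < 1:
            raise ValidationError("detour_factor must be >= 1")


def _haversine_km(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Great-circle km between lon/lat arrays (broadcasting)."""
    lon1, lat1 = np.radians(a[..., 0]), np.radians(a[..., 1])
    lon2, lat2 = np.radians(b[..., 0]), np.radians(b[..., 1])
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def synthetic_travel_time(
    origin: Sequence[float],
    dest: Sequence[float],
    params: SyntheticTravelParams = SyntheticTravelParams(),
    mode: str = "planar",
) -> float:
    """Minutes by car between two points of the same coordinate mode."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(dest, dtype=float)
    if mode == "planar":
        dist = float(np.hypot(*(d - o)))
    elif mode == "wgs84":
        dist = float(_haversine_km(o, d))
    else:
        raise ValidationError(f"unknown coordinate mode {mode!r}")
    return 60.0 * params.detour_factor * dist / params.speed_kmh


@dataclass
class TravelMatrix:
    """m×n matrix of car travel times in minutes.

    Row order follows the DemandSet, column order the HospitalSet; both id
    lists are carried so file round trips and subsetting stay aligned.
    """

    values: np.ndarray
    demand_ids: list[str]
    hospital_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.demand_ids), len(self.hospital_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.demand_ids)} demand × {len(self.hospital_ids)} hospital ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("travel times must all be finite")
        if np.any(self.values < 0):
            raise ValidationError("travel times must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column_index(self, hospital_id: str) -> int:
        try:
            return self.hospital_ids.index(hospital_id)
        except ValueError:
            raise ValidationError(f"unknown hospital id {hospital_id!r}") from None

    def to_csv(self, path: str | Path) -> None:
        """First column ``point_id``, one column per hospital id, minutes
        with 8 significant digits."""
        df = pd.DataFrame(self.values, columns=self.hospital_ids)
        df.insert(0, "point_id", self.demand_ids)
        df.to_csv(path, index=False, float_format="%.8g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TravelMatrix":
        df = pd.read_csv(path, dtype={"point_id": str})
        if "point_id" not in df.columns:
            raise ValidationError(f"{path}: first column must be point_id")
        demand_ids = df["point_id"].tolist()
        hosp = [c for c in df.columns if c != "point_id"]
        return cls(df[hosp].to_numpy(dtype=float), demand_ids, hosp)


class WeightedMatrix(TravelMatrix):
    """Population-weighted travel times, ``w[c,h] = p_c · t[c,h]``
    (person·minutes per km² of density unit — used only as objective
    coefficients, never reported as travel time)."""


def build_matrix(
    demand: DemandSet,
    hospitals: HospitalSet,
    travel_fn: Callable[[Sequence[float], Sequence[float]], float] | None = None,
    params: SyntheticTravelParams | None = None,
) -> TravelMatrix:
    """Evaluate travel time for every (demand, hospital) pair.

    With no ``travel_fn`` the synthetic road-like model is used (vectorized);
    a custom callable ``travel_fn(origin, dest) -> minutes`` is evaluated
    pairwise.
    """
    if demand.m == 0 or hospitals.n == 0:
        raise ValidationError("demand and hospital sets must be non-empty")
    if demand.mode != hospitals.mode:
        raise ValidationError(
            f"mixed coordinate modes: demand {demand.mode!r} vs "
            f"hospitals {hospitals.mode!r}"
        )
    if travel_fn is None:
        p = params or SyntheticTravelParams()
        if demand.mode == "planar":
            diff = demand.xy[:, None, :] - hospitals.xy[None, :, :]
            dist = np.hypot(diff[..., 0], diff[..., 1])
        else:
            dist = _haversine_km(demand.xy[:, None, :], hospitals.xy[None, :, :])
        values = 60.0 * p.detour_factor * dist / p.speed_kmh
    else:
        values = np.empty((demand.m, hospitals.n))
        for i in range(demand.m):
            for j in range(hospitals.n):
                values[i, j] = travel_fn(demand.xy[i], hospitals.xy[j])
    return TravelMatrix(values, list(demand.ids), list(hospitals.ids))


def weight_matrix(T: TravelMatrix, demand: DemandSet) -> WeightedMatrix:
    """Scale row c of the travel matrix by the density p_c."""
    if T.demand_ids != list(demand.ids):
        raise ValidationError("travel matrix rows do not match the demand set ids")
    return WeightedMatrix(
        demand.density[:, None] * T.values, list(T.demand_ids), list(T.hospital_ids)
    )


def nearest_assignment(
    T: TravelMatrix, open_set: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each demand point to its minimum-travel-time open hospital.

    Returns ``(assigned_ids, minutes)`` arrays over demand rows. Ties are
    broken by the first hospital in original column order; the ``open_set``
    argument's own ordering is irrelevant.
    """
    open_ids = set(open_set)
    if not open_ids:
        raise ValidationError("open_set must be non-empty")
    unknown = open_ids - set(T.hospital_ids)
    if unknown:
        raise ValidationError(f"open_set contains unknown hospitals: {sorted(unknown)}")
    cols = [j for j, h in enumerate(T.hospital_ids) if h in open_ids]
    sub = T.values[:, cols]
    arg = np.argmin(sub, axis=1)  # argmin takes the first minimum → column order
    assigned = np.array([T.hospital_ids[cols[j]] for j in arg], dtype=object)
    minutes = sub[np.arange(sub.shape[0]), arg]
    return assigned, minutes


# ---------------------------------------------------------------------------
# External routing adapter contract
# ---------------------------------------------------------------------------

class RoutingAdapter:
    """Contract for sourcing the travel matrix from an external
    matrix-routing engine, with a CSV cache.

    ``request_fn(demand, hospitals) -> (m, n) minutes array`` encapsulates
    the actual service call; the adapter validates the result (finite,
    non-negative, correctly shaped — unreachable pairs must be resolved by
    the routing side, the optimizer requires finite entries) and caches it
    so replays need no network. In synthetic (planar) mode the adapter
    refuses to run: routing engines speak WGS84.
    """

    def __init__(
        self,
        request_fn: Callable[[DemandSet, HospitalSet], np.ndarray] | None = None,
        cache_path: str | Path | None = None,
    ) -> None:
        self.request_fn = request_fn
        self.cache_path = Path(cache_path) if cache_path else None

    def fetch(self, demand: DemandSet, hospitals: HospitalSet) -> TravelMatrix:
        if self.cache_path is not None and self.cache_path.exists():
            T = TravelMatrix.from_csv(self.cache_path)
            if T.demand_ids != list(demand.ids) or T.hospital_ids != list(hospitals.ids):
                raise ValidationError("cached matrix ids do not match the inputs")
            return T
        if demand.mode != "wgs84":
            raise ValidationError(
                "routing adapter is disabled in synthetic (planar) mode; "
                "use the synthetic travel model instead"
            )
        if self.request_fn is None:
            raise ValidationError("no routing endpoint configured and no cache found")
        raw = np.asarray(self.request_fn(demand, hospitals), dtype=float)
        if raw.shape != (demand.m, hospitals.n):
            raise ValidationError(
                f"routing service returned shape {raw.shape}, "
                f"expected {(demand.m, hospitals.n)}"
            )
        if not np.all(np.isfinite(raw)):
            bad = int(np.sum(~np.isfinite(raw)))
            raise ValidationError(
                f"routing service reported {bad} unreachable pairs; the "
                "optimization requires finite travel times for every pair"
            )
        T = TravelMatrix(raw, list(demand.ids), list(hospitals.ids))
        if self.cache_path is not None:
            T.to_csv(self.cache_path)
        return T
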