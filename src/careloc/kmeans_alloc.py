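"""k-means-based facility allocation heuristic.

The heuristic clusters demand points and then maps each cluster to an
existing hospital, yielding a size-k open set comparable to the exact
p-median solution (whose objective it can never beat — a useful sanity
inequality that the test suite asserts).

Two variants are provided, selected by ``KMeansConfig.matching``:

* ``center_argmin`` (default): demand points are clustered in the
  *weighted-travel-time feature space* — observation c is the vector
  (w[c,1], …, w[c,n]) of its weighted travel times to the n hospitals, so
  each hospital is a feature. A cluster's center coordinate for hospital h
  is then the mean weighted travel time of its members to h, and the
  cluster is matched to the hospital minimizing that coordinate. At k=1
  this provably recovers the exact 1-median (argmin_h Σ_c w[c,h]).
* ``geographic``: demand points are clustered in coordinate space with
  population sample weights, and each geographic cluster center is matched
  to the travel-time-nearest hospital.

When two clusters prefer the same hospital, clusters are processed in
descending total-member-population order and each takes its best
not-yet-taken hospital, so exactly k distinct sites are always returned
(a warning is logged whenever this deduplication fires).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .demand import DemandSet
from .errors import ValidationError
from .hospitals import HospitalSet
from .pmedian import AllocationSolution, _solution_from_open
from .travel import SyntheticTravelParams, TravelMatrix, WeightedMatrix, _haversine_km

logger = logging.getLogger(__name__)


@dataclass
class KMeansConfig:
    """k: number of sites to select; n_restarts/max_iter/seed control
    Lloyd's algorithm (k-means++ seeding, best of n_restarts by inertia)."""

    k: int
    n_restarts: int = 10
    max_iter: int = 300
    seed: int = 0
    matching: str = "center_argmin"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be a positive integer")
        if self.n_restarts < 1 or self.max_iter < 1:
            raise ValidationError("n_restarts and max_iter must be >= 1")
        if self.matching not in ("center_argmin", "geographic"):
            raise ValidationError(f"unknown matching rule {self.matching!r}")


@dataclass
class ClusterResult:
    """labels: per-demand cluster index in [0, k); centers: (k, n_features);
    inertia: within-cluster sum of squares."""

    labels: np.ndarray
    centers: np.ndarray
    inertia: float

    def __post_init__(self) -> None:
        if self.inertia < -1e-9:
            raise ValidationError("inertia must be >= 0")
        k = self.centers.shape[0]
        present = np.unique(self.labels)
        if len(present) != k:
            raise ValidationError("every cluster must be non-empty")

    @property
    def k(self) -> int:
        return self.centers.shape[0]


def _fit_kmeans(X: np.ndarray, config: KMeansConfig,
                sample_weight: np.ndarray | None = None) -> ClusterResult:
    km = KMeans(
        n_clusters=config.k,
        n_init=config.n_restarts,
        max_iter=config.max_iter,
        random_state=int(config.seed) % (2**32),
        init="k-means++",
        algorithm="lloyd",
    )
    labels = km.fit_predict(X, sample_weight=sample_weight)
    return ClusterResult(labels=labels, centers=km.cluster_centers_,
                         inertia=float(max(km.inertia_, 0.0)))


def cluster_demand(W: WeightedMatrix, config: KMeansConfig) -> ClusterResult:
    """Cluster demand points with hospitals as features (rows of w)."""
    if not np.all(np.isfinite(W.values)):
        raise ValidationError("weighted matrix must be finite")
    m = len(W.demand_ids)
    if config.k > m:
        raise ValidationError(f"k={config.k} exceeds the {m} demand points")
    return _fit_kmeans(W.values, config)


def match_clusters_to_hospitals(
    result: ClusterResult,
    hospital_ids: Sequence[str],
    matching: str = "center_argmin",
    populations: np.ndarray | None = None,
) -> list[str]:
    """Map each cluster to a distinct hospital via its center vector.

    ``center_argmin``: cluster → hospital with the smallest coordinate in
    the cluster's center (= smallest mean weighted travel time from the
    cluster's members). ``populations`` (per demand point) set the
    deduplication priority; uniform when omitted. Returns exactly k
    distinct hospital ids, in original column order.
    """
    if matching != "center_argmin":
        raise ValidationError(
            "match_clusters_to_hospitals implements the center_argmin rule; "
            "the geographic variant is handled inside kmeans_allocate"
        )
    n = len(hospital_ids)
    k = result.k
    if k > n:
        raise ValidationError(f"k={k} clusters but only {n} hospitals")
    if result.centers.shape[1] != n:
        raise ValidationError("center vectors do not match the hospital count")
    if populations is None:
        populations = np.ones(len(result.labels))
    cluster_pop = np.array(
        [float(populations[result.labels == c].sum()) for c in range(k)]
    )
    # process clusters by descending member population; ties by index
    order = sorted(range(k), key=lambda c: (-cluster_pop[c], c))
    taken: set[int] = set()
    dedup_fired = False
    for c in order:
        prefs = np.argsort(result.centers[c], kind="stable")
        for h in prefs:
            if int(h) not in taken:
                if int(h) != int(prefs[0]):
                    dedup_fired = True
                taken.add(int(h))
                break
    if dedup_fired:
        logger.warning(
            "cluster-to-hospital matching had duplicate targets; "
            "lower-population clusters took their next-best hospital"
        )
    cols = sorted(taken)
    return [hospital_ids[j] for j in cols]


def kmeans_allocate(
    W: WeightedMatrix,
    T: TravelMatrix,
    demand: DemandSet,
    config: KMeansConfig,
    hospitals: HospitalSet | None = None,
    travel_params: SyntheticTravelParams | None = None,
) -> AllocationSolution:
    """Full heuristic: cluster, match clusters to hospitals, evaluate.

    The objective is reported as Σ_c min over selected sites of w — the
    same quantity the exact MILP minimizes — so the two methods are
    directly comparable. ``hospitals`` (and optionally ``travel_params``)
    are required only for the geographic matching variant.
    """
    if T.hospital_ids != W.hospital_ids or T.demand_ids != W.demand_ids:
        raise ValidationError("T and W must share demand and hospital ids")
    if config.matching == "center_argmin":
        result = cluster_demand(W, config)
        open_ids = match_clusters_to_hospitals(
            result, W.hospital_ids, "center_argmin", populations=demand.population
        )
    else:
        if hospitals is None:
            raise ValidationError("geographic matching requires the HospitalSet")
        if config.k > demand.m:
            raise ValidationError(f"k={config.k} exceeds the {demand.m} demand points")
        params = travel_params or SyntheticTravelParams()
        result = _fit_kmeans(demand.xy, config, sample_weight=demand.population)
        # travel time from each geographic center to each hospital
        if demand.mode == "planar":
            diff = result.centers[:, None, :] - hospitals.xy[None, :, :]
            dist = np.hypot(diff[..., 0], diff[..., 1])
        else:
            dist = _haversine_km(result.centers[:, None, :], hospitals.xy[None, :, :])
        center_minutes = 60.0 * params.detour_factor * dist / params.speed_kmh
        proxy = ClusterResult(labels=result.labels, centers=center_minutes,
                              inertia=result.inertia)
        open_ids = match_clusters_to_hospitals(
            proxy, W.hospital_ids, "center_argmin", populations=demand.population
        )
    col = {h: j for j, h in enumerate(W.hospital_ids)}
    sol = _solution_from_open(
        W, [col[h] for h in open_ids],
        meta={
            "method": "kmeans",
            "matching": config.matching,
            "k": config.k,
            "n_restarts": config.n_restarts,
            "seed": config.seed,
        },
    )
    return sol
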