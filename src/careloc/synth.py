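"""Synthetic country generator.

Downstream stages (travel matrices, p-median optimization, accessibility
metrics) were designed for a real national dataset — an administrative
partition with heterogeneous population densities, a hexagonal demand grid,
and a curated list of candidate hospital sites — that is not publicly
deposited. This module generates planar geographies with the same
statistical structure so that the whole pipeline runs and can be tested
offline:

* a rectangular country tiled by Voronoi "administrative regions", each
  assigned one of three urbanization classes (urban / intermediate / rural)
  and a class-specific population density;
* a pointy-top hexagonal lattice of demand centroids clipped to the
  rectangle, each centroid inheriting its region's density and class;
* candidate hospital sites sampled at demand centroids with a configurable
  bias toward dense cells, a subset of which is flagged as currently
  providing the service (the "pediatric" sites).

Everything is deterministic given the config seed. Geometry is planar km —
projection effects are deliberately excluded so geometric tests have exact
oracles; the real-geo path lives in :mod:`careloc.demand`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.strtree import STRtree

from .demand import URBANIZATION_CLASSES, DemandSet
from .errors import ValidationError
from .hospitals import HospitalSet

# Default density ranges (persons/km²) per urbanization class, spanning the
# realistic range of European NUTS-3 regions: dense city districts reach a
# few thousand, remote rural districts a few tens.
DEFAULT_DENSITY_RANGES = {
    "urban": (500.0, 3000.0),
    "intermediate": (150.0, 500.0),
    "rural": (40.0, 150.0),
}


@dataclass
class SyntheticCountryConfig:
    """Parameters of the generated country.

    The defaults mirror a Germany-sized setting at one tenth of its size:
    a ~108,000 km² rectangle covered by ~1100 hexagon centroids (vs ~10,900
    for Germany at the coarse grid), 100 candidate hospitals of which 31
    provide the service (vs 1023 / 315), 40 regions (vs ~400 NUTS-3), and
    class shares close to the European urban/intermediate/rural mix.
    """

    country_width_km: float = 300.0
    country_height_km: float = 360.0
    n_regions: int = 40
    class_shares: tuple[float, float, float] = (0.25, 0.40, 0.35)
    density_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_RANGES)
    )
    hex_spacing_km: float = 10.5
    n_hospitals: int = 100
    n_service: int = 31
    site_density_bias: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.country_width_km <= 0 or self.country_height_km <= 0:
            raise ValidationError("country rectangle must have positive area")
        if self.n_regions < 1:
            raise ValidationError("n_regions must be >= 1")
        shares = np.asarray(self.class_shares, dtype=float)
        if shares.shape != (3,) or np.any(shares < 0):
            raise ValidationError("class_shares must be three non-negative reals")
        if abs(float(shares.sum()) - 1.0) > 1e-9:
            raise ValidationError(
                f"class_shares must sum to 1 (got {float(shares.sum())!r})"
            )
        for cls in URBANIZATION_CLASSES:
            lo, hi = self.density_ranges[cls]
            if not (0 < lo < hi):
                raise ValidationError(
                    f"density range for {cls!r} must satisfy 0 < low < high"
                )
        if self.hex_spacing_km <= 0:
            raise ValidationError("hex_spacing_km must be > 0")
        if self.n_hospitals < 1:
            raise ValidationError("n_hospitals must be >= 1")
        if not 0 <= self.n_service <= self.n_hospitals:
            raise ValidationError("need 0 <= n_service <= n_hospitals")
        if self.site_density_bias < 0:
            raise ValidationError("site_density_bias must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["class_shares"] = list(self.class_shares)
        d["density_ranges"] = {k: list(v) for k, v in self.density_ranges.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCountryConfig":
        d = dict(d)
        if "class_shares" in d:
            d["class_shares"] = tuple(float(s) for s in d["class_shares"])
        if "density_ranges" in d:
            d["density_ranges"] = {
                k: (float(v[0]), float(v[1])) for k, v in d["density_ranges"].items()
            }
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticCountryConfig":
        """Read a config from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        cfg = cls.from_dict(data)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class Region:
    region_id: int
    urbanization: str
    density: float
    polygon: Polygon


@dataclass
class RegionSet:
    regions: list[Region]
    width_km: float
    height_km: float

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def total_area(self) -> float:
        return sum(r.polygon.area for r in self.regions)


def generate_regions(config: SyntheticCountryConfig) -> RegionSet:
    """Partition the country rectangle into Voronoi regions with classes
    and densities.

    Region seeds are sampled uniformly over the rectangle; their Voronoi
    cells (clipped to the rectangle) form the partition, giving irregular
    convex shapes resembling administrative districts. Each region draws an
    urbanization class from ``class_shares`` and a density uniformly from
    its class range. Deterministic given ``config.seed``.
    """
    config.validate()
    w, h = config.country_width_km, config.country_height_km
    rng = np.random.default_rng(config.seed)
    seeds = rng.uniform((0, 0), (w, h), size=(config.n_regions, 2))
    classes = rng.choice(
        np.array(URBANIZATION_CLASSES, dtype=object),
        size=config.n_regions,
        p=np.asarray(config.class_shares, dtype=float),
    )
    densities = np.array(
        [rng.uniform(*config.density_ranges[str(c)]) for c in classes]
    )

    rect = box(0.0, 0.0, w, h)
    if config.n_regions == 1:
        polys = [rect]
    else:
        cells = shapely.voronoi_polygons(
            MultiPoint([tuple(p) for p in seeds]), extend_to=rect
        )
        # Map each Voronoi cell back to the seed it contains; clip to the
        # rectangle so the cells tile it exactly.
        polys: list[Polygon | None] = [None] * config.n_regions
        cell_list = list(cells.geoms)
        tree = STRtree(cell_list)
        for i, (sx, sy) in enumerate(seeds):
            pt = Point(sx, sy)
            for j in tree.query(pt):
                if cell_list[j].covers(pt):
                    polys[i] = cell_list[j].intersection(rect)
                    break
            if polys[i] is None:  # numeric edge: fall back to nearest cell
                j = min(range(len(cell_list)), key=lambda j: cell_list[j].distance(pt))
                polys[i] = cell_list[j].intersection(rect)

    regions = [
        Region(region_id=i, urbanization=str(classes[i]), density=float(densities[i]),
               polygon=polys[i])
        for i in range(config.n_regions)
    ]
    return RegionSet(regions=regions, width_km=w, height_km=h)


def hex_cell_area(spacing_km: float) -> float:
    """Area (km²) of the hexagonal cell owned by each lattice centroid.

    For a triangular lattice with nearest-neighbour distance ``s`` the
    Voronoi cell is a regular hexagon of area ``s²·√3/2``.
    """
    return (math.sqrt(3.0) / 2.0) * spacing_km**2


def hex_lattice(width_km: float, height_km: float, spacing_km: float) -> np.ndarray:
    """Centroids of a pointy-top hexagonal lattice clipped to the rectangle.

    Rows are ``s·√3/2`` apart; odd rows are shifted by ``s/2``. The lattice
    is anchored at ``(s/2, s·√3/4)`` so a sufficiently large spacing still
    leaves one interior centroid.
    """
    dx = spacing_km
    dy = spacing_km * math.sqrt(3.0) / 2.0
    pts = []
    j = 0
    y = dy / 2.0
    while y <= height_km:
        offset = dx / 2.0 + (dx / 2.0 if j % 2 else 0.0)
        x = offset
        while x <= width_km:
            pts.append((x, y))
            x += dx
        j += 1
        y = dy / 2.0 + j * dy
    return np.array(pts, dtype=float).reshape(-1, 2)


def generate_demand_grid(
    regions: RegionSet, hex_spacing_km: float, seed: int = 0
) -> DemandSet:
    """Lay the hexagonal demand grid over the country and join region
    attributes.

    Each centroid carries the density and urbanization class of the region
    containing it (boundary ties broken by lowest region_id) and the full
    hexagon cell area. ``seed`` is accepted for interface symmetry; the
    grid itself is deterministic.
    """
    if hex_spacing_km <= 0:
        raise ValidationError("hex_spacing_km must be > 0")
    pts = hex_lattice(regions.width_km, regions.height_km, hex_spacing_km)
    if len(pts) == 0:
        raise ValidationError(
            "hex spacing exceeds the country extent: empty demand grid"
        )
    area = hex_cell_area(hex_spacing_km)

    polys = [r.polygon for r in regions.regions]
    tree = STRtree(polys)
    region_idx = np.empty(len(pts), dtype=int)
    for i, (x, y) in enumerate(pts):
        pt = Point(x, y)
        hits = [int(j) for j in tree.query(pt) if polys[j].covers(pt)]
        if hits:
            region_idx[i] = min(hits)  # boundary tie → lowest region_id
        else:  # float slack on shared edges: nearest region, deterministic
            region_idx[i] = min(
                range(len(polys)), key=lambda j: (polys[j].distance(pt), j)
            )

    ndigits = max(4, len(str(len(pts) - 1)))
    ids = [f"c{i:0{ndigits}d}" for i in range(len(pts))]
    return DemandSet(
        ids=ids,
        xy=pts,
        region_id=np.array([str(regions.regions[j].region_id) for j in region_idx],
                           dtype=object),
        urbanization=np.array(
            [regions.regions[j].urbanization for j in region_idx], dtype=object
        ),
        density=np.array([regions.regions[j].density for j in region_idx]),
        cell_area=np.full(len(pts), area),
        mode="planar",
    )


def _biased_choice(
    rng: np.random.Generator, weights: np.ndarray, size: int
) -> np.ndarray:
    p = weights / weights.sum()
    return rng.choice(len(weights), size=size, replace=False, p=p)


def generate_hospitals(
    demand: DemandSet,
    n_hospitals: int,
    n_service: int,
    site_density_bias: float = 1.0,
    seed: int = 0,
) -> HospitalSet:
    """Sample candidate hospital sites at demand centroids.

    Sites are drawn without replacement with probability proportional to
    ``density**site_density_bias`` (bias 0 → uniform), emulating the
    concentration of hospitals in populous areas. Exactly ``n_service``
    of them are flagged as current service (pediatric) sites, drawn by the
    same biased sampling among the sites. Hospitals coincide with demand
    centroids by construction, so zero travel time is attainable.
    """
    if n_hospitals > demand.m:
        raise ValidationError(
            f"n_hospitals={n_hospitals} exceeds the {demand.m} demand points"
        )
    if not 0 <= n_service <= n_hospitals:
        raise ValidationError("need 0 <= n_service <= n_hospitals")
    if site_density_bias < 0:
        raise ValidationError("site_density_bias must be >= 0")
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore"):
        weights = np.power(demand.density, site_density_bias, dtype=float)
    if not np.all(np.isfinite(weights)) or weights.sum() <= 0:
        weights = np.ones(demand.m)
    chosen = np.sort(_biased_choice(rng, weights, n_hospitals))
    ndigits = max(4, len(str(n_hospitals - 1)))
    ids = [f"h{k:0{ndigits}d}" for k in range(n_hospitals)]
    ped = np.zeros(n_hospitals, dtype=bool)
    if n_service > 0:
        sub = weights[chosen]
        ped[_biased_choice(rng, sub, n_service)] = True
    return HospitalSet(
        ids=ids,
        xy=demand.xy[chosen],
        pediatric=ped,
        mode=demand.mode,
        demand_point_id=np.array([demand.ids[j] for j in chosen], dtype=object),
    )


def generate_country(
    config: SyntheticCountryConfig,
) -> tuple[RegionSet, DemandSet, HospitalSet]:
    """Convenience wrapper running all three generation stages."""
    regions = generate_regions(config)
    demand = generate_demand_grid(regions, config.hex_spacing_km, seed=config.seed)
    hospitals = generate_hospitals(
        demand,
        config.n_hospitals,
        config.n_service,
        config.site_density_bias,
        seed=config.seed + 1,
    )
    return regions, demand, hospitals


def write_sidecar(path: str | Path, config: SyntheticCountryConfig, **extra) -> Path:
    """Write a ``<path>.meta.json`` provenance sidecar with the config and
    seed that produced an artifact."""
    path = Path(path)
    meta = {"config": config.to_dict(), "seed": config.seed}
    meta.update(extra)
    side = path.with_name(path.name + ".meta.json")
    side.write_text(json.dumps(meta, sort_keys=True, indent=1))
    return side
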