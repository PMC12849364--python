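"""Demand-side data model.

A demand point stands in for the homes of patients in one cell of a
hexagonal grid laid over the country: it carries the cell centroid, the
population density of the administrative region containing it, the cell
area, and the region's urban/rural class. Cell population is always
``density × area``; fractional persons are kept deliberately so that
population-weighted statistics are exact (rounding happens only at
presentation).

Two coordinate modes exist. Synthetic geographies are planar (km), which
keeps geometric oracles exact; real geographies use WGS84 degrees and are
reached through :func:`h3_demand_adapter`, which requires an optional
hexagonal-indexing backend.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import RealGeoUnavailableError, ValidationError

URBANIZATION_CLASSES = ("urban", "intermediate", "rural")
MODES = ("planar", "wgs84")

#: CSV column names per coordinate mode (x/y are km, lon/lat degrees).
_CSV_COORDS = {"planar": ("x", "y"), "wgs84": ("lon", "lat")}


def estimate_population(cell_area: float, density: float):
    """Population of a grid cell: ``area [km²] × density [persons/km²]``.

    Accepts scalars or numpy arrays; no rounding is applied.
    """
    area = np.asarray(cell_area, dtype=float)
    dens = np.asarray(density, dtype=float)
    if np.any(area <= 0):
        raise ValidationError("cell_area must be > 0")
    if np.any(dens < 0):
        raise ValidationError("density must be >= 0")
    out = area * dens
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DemandPoint:
    """A single demand point (one hexagon centroid)."""

    point_id: str
    x: float
    y: float
    region_id: str
    urbanization: str
    density: float
    cell_area: float

    @property
    def population(self) -> float:
        return self.density * self.cell_area


@dataclass
class DemandSet:
    """Ordered collection of demand points, stored columnar.

    Attributes
    ----------
    ids : list of unique point identifiers (row order is significant; the
        travel matrix follows it).
    xy : (m, 2) float array, km (planar) or lon/lat degrees (wgs84).
    region_id, urbanization : per-point labels.
    density : persons per km² (p_c).
    cell_area : km² per grid cell.
    mode : "planar" or "wgs84".
    """

    ids: list[str]
    xy: np.ndarray
    region_id: np.ndarray
    urbanization: np.ndarray
    density: np.ndarray
    cell_area: np.ndarray
    mode: str = "planar"

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.ids), 2)
        self.region_id = np.asarray(self.region_id, dtype=object)
        self.urbanization = np.asarray(self.urbanization, dtype=object)
        self.density = np.asarray(self.density, dtype=float)
        self.cell_area = np.asarray(self.cell_area, dtype=float)
        if self.mode not in MODES:
            raise ValidationError(f"unknown coordinate mode {self.mode!r}")
        if len(self.ids) < 1:
            raise ValidationError("a DemandSet needs at least one point")
        seen: set[str] = set()
        for pid in self.ids:
            if pid in seen:
                raise ValidationError(f"duplicate point_id {pid!r}")
            seen.add(pid)
        for name in ("region_id", "urbanization", "density", "cell_area"):
            if len(getattr(self, name)) != len(self.ids):
                raise ValidationError(f"column {name!r} length mismatch")
        if np.any(self.density < 0):
            raise ValidationError("densities must be >= 0")
        if np.any(self.cell_area <= 0):
            raise ValidationError("cell areas must be > 0")
        bad = set(self.urbanization) - set(URBANIZATION_CLASSES)
        if bad:
            raise ValidationError(f"unknown urbanization classes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.ids)

    @property
    def population(self) -> np.ndarray:
        return self.density * self.cell_area

    def point(self, i: int) -> DemandPoint:
        return DemandPoint(
            self.ids[i],
            float(self.xy[i, 0]),
            float(self.xy[i, 1]),
            str(self.region_id[i]),
            str(self.urbanization[i]),
            float(self.density[i]),
            float(self.cell_area[i]),
        )

    def to_dataframe(self):
        import pandas as pd

        xcol, ycol = _CSV_COORDS[self.mode]
        return pd.DataFrame(
            {
                "point_id": self.ids,
                xcol: self.xy[:, 0],
                ycol: self.xy[:, 1],
                "region_id": [str(r) for r in self.region_id],
                "urbanization": [str(u) for u in self.urbanization],
                "density_per_km2": self.density,
                "area_km2": self.cell_area,
            }
        )


# ---------------------------------------------------------------------------
# I/O: GeoJSON (RFC 7946) and flat CSV
# ---------------------------------------------------------------------------

_REQUIRED_PROPS = ("region_id", "urbanization", "density_per_km2", "area_km2")


def save_demand(demand: DemandSet, path: str | Path) -> None:
    """Write a DemandSet to GeoJSON (``.geojson``/``.json``) or CSV (``.csv``).

    Units: coordinates km (planar) or degrees (wgs84); density persons/km²;
    area km².
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        features = []
        for i, pid in enumerate(demand.ids):
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(demand.xy[i, 0]), float(demand.xy[i, 1])],
                    },
                    "properties": {
                        "point_id": pid,
                        "region_id": str(demand.region_id[i]),
                        "urbanization": str(demand.urbanization[i]),
                        "density_per_km2": float(demand.density[i]),
                        "area_km2": float(demand.cell_area[i]),
                        "population": float(demand.density[i] * demand.cell_area[i]),
                    },
                }
            )
        doc = {
            "type": "FeatureCollection",
            "careloc:mode": demand.mode,
            "features": features,
        }
        path.write_text(json.dumps(doc, sort_keys=True))
    elif path.suffix.lower() == ".csv":
        df = demand.to_dataframe()
        df["population"] = demand.population
        df.to_csv(path, index=False)
    else:
        raise ValidationError(f"unsupported demand file suffix {path.suffix!r}")


def _check_population(pid: str, stored, density: float, area: float) -> None:
    if stored is None or stored == "":
        return
    expect = density * area
    tol = 1e-9 * max(1.0, abs(expect))
    if abs(float(stored) - expect) > tol:
        raise ValidationError(
            f"point {pid!r}: stored population {stored} != density×area {expect}"
        )


def load_demand(path: str | Path, mode: str | None = None) -> DemandSet:
    """Load a DemandSet written by :func:`save_demand`.

    ``mode`` may be given to assert the expected coordinate mode; mixing
    modes (e.g. a wgs84 file loaded as planar) is rejected. Stored
    populations, when present, are checked against density × area.
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        doc = json.loads(path.read_text())
        file_mode = doc.get("careloc:mode", "planar")
        ids, xy, rid, urb, dens, area = [], [], [], [], [], []
        for k, feat in enumerate(doc.get("features", [])):
            props = feat.get("properties", {})
            pid = props.get("point_id", f"<feature {k}>")
            missing = [p for p in _REQUIRED_PROPS if p not in props]
            if missing:
                raise ValidationError(
                    f"feature {pid!r} missing required properties: {missing}"
                )
            coords = feat["geometry"]["coordinates"]
            _check_population(
                pid, props.get("population"), float(props["density_per_km2"]),
                float(props["area_km2"]),
            )
            ids.append(str(pid))
            xy.append([float(coords[0]), float(coords[1])])
            rid.append(str(props["region_id"]))
            urb.append(str(props["urbanization"]))
            dens.append(float(props["density_per_km2"]))
            area.append(float(props["area_km2"]))
    elif path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise ValidationError(f"{path}: empty demand CSV")
        header = rows[0].keys()
        if {"x", "y"} <= set(header):
            file_mode, (xc, yc) = "planar", ("x", "y")
        elif {"lon", "lat"} <= set(header):
            file_mode, (xc, yc) = "wgs84", ("lon", "lat")
        else:
            raise ValidationError(f"{path}: need x/y or lon/lat coordinate columns")
        ids, xy, rid, urb, dens, area = [], [], [], [], [], []
        for k, row in enumerate(rows):
            pid = row.get("point_id") or f"<row {k}>"
            missing = [p for p in _REQUIRED_PROPS if not row.get(p)]
            if missing:
                raise ValidationError(f"record {pid!r} missing fields: {missing}")
            _check_population(
                pid, row.get("population"), float(row["density_per_km2"]),
                float(row["area_km2"]),
            )
            ids.append(str(pid))
            xy.append([float(row[xc]), float(row[yc])])
            rid.append(str(row["region_id"]))
            urb.append(str(row["urbanization"]))
            dens.append(float(row["density_per_km2"]))
            area.append(float(row["area_km2"]))
    else:
        raise ValidationError(f"unsupported demand file suffix {path.suffix!r}")

    if mode is not None and mode != file_mode:
        raise ValidationError(
            f"mode mismatch: requested {mode!r} but file is {file_mode!r}"
        )
    return DemandSet(
        ids=ids,
        xy=np.array(xy),
        region_id=np.array(rid, dtype=object),
        urbanization=np.array(urb, dtype=object),
        density=np.array(dens),
        cell_area=np.array(area),
        mode=file_mode,
    )


# ---------------------------------------------------------------------------
# Real-geo adapter (optional backend)
# ---------------------------------------------------------------------------

def h3_demand_adapter(country_polygon, resolution: int) -> DemandSet:
    """Build a DemandSet from hexagonal-index cell centroids covering a
    WGS84 polygon.

    Requires the ``h3`` indexing library and ``pyproj`` (cell areas are
    computed in an equal-area projection, EPSG:3035). Densities and
    urbanization labels are initialized empty-equivalent (density 0,
    class "intermediate") and are meant to be joined from user-supplied
    region tables afterwards. Raises
    :class:`~careloc.errors.RealGeoUnavailableError` when the backend is
    absent; the synthetic planar path does not depend on it.
    """
    if not 0 <= int(resolution) <= 15:
        raise ValidationError("hex resolution must be in 0..15")
    try:
        import h3  # type: ignore
        from pyproj import Geod  # type: ignore  # noqa: F401
        from pyproj import Transformer  # type: ignore  # noqa: F401
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise RealGeoUnavailableError(
            "real-geo mode unavailable: the 'h3' and 'pyproj' packages are "
            "required for hexagonal coverage of a WGS84 polygon; install them "
            "or use synthetic (planar) mode"
        ) from exc

    # pragma: no cover — exercised only when the optional backend is present.
    import shapely.geometry as sgeom

    poly = sgeom.shape(country_polygon) if isinstance(country_polygon, dict) else country_polygon
    cells = h3.geo_to_cells(poly, res=int(resolution))
    transformer = Transformer.from_crs("EPSG:4326", "EPSG:3035", always_xy=True)
    ids, xy, areas = [], [], []
    for cell in sorted(cells):
        lat, lon = h3.cell_to_latlng(cell)
        boundary = h3.cell_to_boundary(cell)
        ring = [transformer.transform(lng_, lat_) for lat_, lng_ in boundary]
        area_km2 = abs(sgeom.Polygon(ring).area) / 1e6
        ids.append(cell)
        xy.append([lon, lat])
        areas.append(area_km2)
    m = len(ids)
    return DemandSet(
        ids=ids,
        xy=np.array(xy),
        region_id=np.array([""] * m, dtype=object),
        urbanization=np.array(["intermediate"] * m, dtype=object),
        density=np.zeros(m),
        cell_area=np.array(areas),
        mode="wgs84",
    )
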