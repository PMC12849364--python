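"""Candidate facility sites.

A HospitalSet holds every acute-care site eligible to receive the
specialized (pediatric) service; the ``pediatric`` flag marks the subset
currently providing it (the "current" service configuration that
optimization scenarios compare against or pin).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .demand import MODES, _CSV_COORDS
from .errors import ValidationError


@dataclass
class HospitalSet:
    """Columnar set of candidate hospital sites.

    ids : unique site identifiers (column order of the travel matrix).
    xy : (n, 2) coordinates, km (planar) or lon/lat (wgs84).
    pediatric : boolean flags for the current service subset.
    demand_point_id : for synthetic sites, the demand centroid each site
        coincides with ("" when not applicable).
    """

    ids: list[str]
    xy: np.ndarray
    pediatric: np.ndarray
    mode: str = "planar"
    demand_point_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.ids), 2)
        self.pediatric = np.asarray(self.pediatric, dtype=bool)
        if self.mode not in MODES:
            raise ValidationError(f"unknown coordinate mode {self.mode!r}")
        if len(self.ids) < 1:
            raise ValidationError("a HospitalSet needs at least one site")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("hospital ids must be unique")
        if len(self.pediatric) != len(self.ids):
            raise ValidationError("pediatric flag length mismatch")
        if self.demand_point_id is None:
            self.demand_point_id = np.array([""] * len(self.ids), dtype=object)
        else:
            self.demand_point_id = np.asarray(self.demand_point_id, dtype=object)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def service_ids(self) -> list[str]:
        """Ids of the sites currently flagged as service (pediatric) sites."""
        return [h for h, f in zip(self.ids, self.pediatric) if f]


def save_hospitals(hospitals: HospitalSet, path: str | Path) -> None:
    """Write to GeoJSON (Point features, ``pediatric`` property) or CSV."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        features = [
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(hospitals.xy[i, 0]), float(hospitals.xy[i, 1])],
                },
                "properties": {
                    "hospital_id": hid,
                    "pediatric": bool(hospitals.pediatric[i]),
                    "demand_point_id": str(hospitals.demand_point_id[i]),
                },
            }
            for i, hid in enumerate(hospitals.ids)
        ]
        doc = {
            "type": "FeatureCollection",
            "careloc:mode": hospitals.mode,
            "features": features,
        }
        path.write_text(json.dumps(doc, sort_keys=True))
    elif path.suffix.lower() == ".csv":
        xc, yc = _CSV_COORDS[hospitals.mode]
        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["hospital_id", xc, yc, "pediatric", "demand_point_id"])
            for i, hid in enumerate(hospitals.ids):
                wr.writerow(
                    [
                        hid,
                        repr(float(hospitals.xy[i, 0])),
                        repr(float(hospitals.xy[i, 1])),
                        int(hospitals.pediatric[i]),
                        hospitals.demand_point_id[i],
                    ]
                )
    else:
        raise ValidationError(f"unsupported hospital file suffix {path.suffix!r}")


def load_hospitals(path: str | Path, mode: str | None = None) -> HospitalSet:
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        doc = json.loads(path.read_text())
        file_mode = doc.get("careloc:mode", "planar")
        ids, xy, ped, dpid = [], [], [], []
        for k, feat in enumerate(doc.get("features", [])):
            props = feat.get("properties", {})
            hid = props.get("hospital_id")
            if hid is None:
                raise ValidationError(f"feature {k} missing hospital_id")
            if "pediatric" not in props:
                raise ValidationError(f"feature {hid!r} missing pediatric flag")
            ids.append(str(hid))
            xy.append([float(c) for c in feat["geometry"]["coordinates"]])
            ped.append(bool(props["pediatric"]))
            dpid.append(str(props.get("demand_point_id", "")))
    elif path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        if not rows:
            raise ValidationError(f"{path}: empty hospital CSV")
        header = set(rows[0].keys())
        if {"x", "y"} <= header:
            file_mode, (xc, yc) = "planar", ("x", "y")
        elif {"lon", "lat"} <= header:
            file_mode, (xc, yc) = "wgs84", ("lon", "lat")
        else:
            raise ValidationError(f"{path}: need x/y or lon/lat coordinate columns")
        ids, xy, ped, dpid = [], [], [], []
        for k, row in enumerate(rows):
            hid = row.get("hospital_id") or f"<row {k}>"
            if row.get("pediatric") in (None, ""):
                raise ValidationError(f"record {hid!r} missing pediatric flag")
            ids.append(str(hid))
            xy.append([float(row[xc]), float(row[yc])])
            ped.append(bool(int(row["pediatric"])))
            dpid.append(row.get("demand_point_id", ""))
    else:
        raise ValidationError(f"unsupported hospital file suffix {path.suffix!r}")

    if mode is not None and mode != file_mode:
        raise ValidationError(
            f"mode mismatch: requested {mode!r} but file is {file_mode!r}"
        )
    return HospitalSet(
        ids=ids,
        xy=np.array(xy),
        pediatric=np.array(ped, dtype=bool),
        mode=file_mode,
        demand_point_id=np.array(dpid, dtype=object),
    )
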