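"""Climatic stratification of occurrence records.

Records are placed into three independent strata: (i) climatic regions
found by clustering grid cells on temperature and precipitation
seasonality (six clusters by default), (ii) five 10° latitudinal bands
between 25°N and 25°S, and (iii) three broad subcontinental zones —
Central America & the Caribbean (CAC), western South America (WSA) and
eastern South America (ESA) — via point-in-polygon tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from sklearn.cluster import KMeans

__all__ = [
    "RegionModel",
    "ZONE_ORDER",
    "seasonality_features",
    "fit_regions",
    "nearest_cell",
    "assign_region",
    "assign_band",
    "assign_zone",
    "assign_strata",
    "default_zone_polygons",
    "load_zone_polygons",
]

PRECIP_COLS = [f"prec_{m:02d}" for m in range(1, 13)]
TEMP_COLS = [f"temp_{m:02d}" for m in range(1, 13)]

# Point-in-polygon test order for boundary points.
ZONE_ORDER = ("CAC", "WSA", "ESA")


def seasonality_features(precip: Sequence[float], temp: Sequence[float]) -> np.ndarray:
    """24-feature seasonality vector for one grid cell.

    Precipitation enters as monthly shares of the annual total (scale-free:
    a wet and a dry cell with the same rhythm look alike; an all-zero year
    degrades to uniform shares), temperature as within-cell z-scores (a
    constant regime contributes zeros).
    """
    p = np.asarray(precip, dtype=float)
    t = np.asarray(temp, dtype=float)
    if p.size != 12 or t.size != 12:
        raise ValueError("need 12 monthly values for precipitation and temperature")
    total = p.sum()
    shares = p / total if total > 0 else np.full(12, 1.0 / 12.0)
    sd = t.std()
    z = (t - t.mean()) / sd if sd > 1e-12 else np.zeros(12)
    return np.concatenate([shares, z])


@dataclass
class RegionModel:
    """Fitted regionalization: centroids in feature space + the cell map."""

    k: int
    centroids: np.ndarray
    cell_regions: dict[int, int]  # cell_id -> region id (1..k)
    seed: int
    inertia: float

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps({
            "k": self.k, "seed": self.seed, "inertia": self.inertia,
            "centroids": self.centroids.tolist(),
            "cell_regions": {str(c): r for c, r in self.cell_regions.items()},
        }, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def _grid_features(grid: pd.DataFrame) -> np.ndarray:
    return np.vstack([
        seasonality_features(row[PRECIP_COLS].to_numpy(float),
                             row[TEMP_COLS].to_numpy(float))
        for _, row in grid.iterrows()
    ])


def fit_regions(
    grid: pd.DataFrame, k: int = 6, seed: int = 0, n_init: int = 10
) -> RegionModel:
    """Cluster grid cells into ``k`` climatic regions (best of ``n_init``
    seeded k-means restarts on the seasonality features).

    Cells are processed in cell_id order, so the partition does not depend
    on the input row order.
    """
    g = grid.sort_values("cell_id").reset_index(drop=True)
    if len(g) < k:
        raise ValueError(f"need at least k={k} cells, got {len(g)}")
    feats = _grid_features(g)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(feats)
    # canonical region ids: order clusters by first appearance in cell order
    order: dict[int, int] = {}
    for lbl in raw:
        if lbl not in order:
            order[lbl] = len(order) + 1
    cell_regions = {int(c): order[l] for c, l in zip(g["cell_id"], raw)}
    centroids = np.vstack([km.cluster_centers_[lbl]
                           for lbl, _ in sorted(order.items(), key=lambda kv: kv[1])])
    return RegionModel(k=k, centroids=centroids, cell_regions=cell_regions,
                       seed=seed, inertia=float(km.inertia_))


_EARTH_R = 6371.0


def _haversine(lat1, lon1, lat2, lon2):
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * _EARTH_R * np.arcsin(np.sqrt(a))


def nearest_cell(
    latitude: float | None,
    longitude: float | None,
    grid: pd.DataFrame,
    max_outside_deg: float = 5.0,
) -> int | None:
    """Nearest grid cell by great-circle distance; ties take the lowest
    cell id.  Points more than ``max_outside_deg`` outside the grid's
    bounding box are left unassigned with a warning."""
    if latitude is None or longitude is None or latitude != latitude:
        return None
    g = grid.sort_values("cell_id")
    lat0, lat1 = g["latitude"].min(), g["latitude"].max()
    lon0, lon1 = g["longitude"].min(), g["longitude"].max()
    if (latitude < lat0 - max_outside_deg or latitude > lat1 + max_outside_deg
            or longitude < lon0 - max_outside_deg or longitude > lon1 + max_outside_deg):
        warnings.warn(f"point ({latitude}, {longitude}) lies >"
                      f"{max_outside_deg}° outside the climate grid; unassigned")
        return None
    d = _haversine(latitude, longitude,
                   g["latitude"].to_numpy(float), g["longitude"].to_numpy(float))
    return int(g["cell_id"].to_numpy()[int(np.argmin(d))])  # argmin: first = lowest id


def assign_region(
    latitude: float | None,
    longitude: float | None,
    model: RegionModel,
    grid: pd.DataFrame,
    max_outside_deg: float = 5.0,
) -> int | None:
    """Region of the nearest grid cell; see :func:`nearest_cell`."""
    cell = nearest_cell(latitude, longitude, grid, max_outside_deg)
    return None if cell is None else model.cell_regions[cell]


def assign_band(latitude: float | None) -> int | None:
    """10° latitudinal band id between 25°N and 25°S, else None.

    Bands are half-open on their southern edge except the last:
    1 = (15, 25], 2 = (5, 15], 3 = (−5, 5], 4 = (−15, −5], 5 = [−25, −15].
    """
    if latitude is None or latitude != latitude or not -90 <= latitude <= 90:
        return None
    if latitude > 25.0 or latitude < -25.0:
        return None
    for i, lo in enumerate((15.0, 5.0, -5.0, -15.0), start=1):
        if latitude > lo:
            return i
    return 5


def default_zone_polygons() -> dict:
    """Coarse CAC/WSA/ESA boxes as a GeoJSON FeatureCollection.

    A deliberately simple stand-in for the IPCC reference subcontinental
    zones; real analyses should supply the authoritative polygons.
    """
    def box(lon0, lat0, lon1, lat1):
        return {"type": "Polygon", "coordinates": [[
            [lon0, lat0], [lon1, lat0], [lon1, lat1], [lon0, lat1], [lon0, lat0]]]}
    return {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {"zone": "CAC"},
             "geometry": box(-118.0, 7.0, -59.0, 33.0)},
            {"type": "Feature", "properties": {"zone": "WSA"},
             "geometry": box(-82.0, -56.0, -66.0, 7.0)},
            {"type": "Feature", "properties": {"zone": "ESA"},
             "geometry": box(-66.0, -56.0, -33.0, 7.0)},
        ],
    }


def load_zone_polygons(geojson: dict | str | Path) -> dict[str, object]:
    """GeoJSON FeatureCollection → {zone name: shapely geometry}."""
    if isinstance(geojson, (str, Path)):
        geojson = json.loads(Path(geojson).read_text())
    out = {}
    for feat in geojson["features"]:
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"invalid polygon for zone {feat['properties']}")
        out[feat["properties"]["zone"]] = geom
    return out


def assign_zone(
    latitude: float | None,
    longitude: float | None,
    polygons: Mapping[str, object],
) -> str | None:
    """Zone containing the point; boundary points go to the first matching
    zone in CAC, WSA, ESA order."""
    if latitude is None or longitude is None or latitude != latitude:
        return None
    pt = Point(longitude, latitude)
    names = [z for z in ZONE_ORDER if z in polygons]
    names += [z for z in polygons if z not in names]
    for name in names:
        if polygons[name].covers(pt):
            return name
    return None


def assign_strata(
    records: pd.DataFrame,
    model: RegionModel,
    grid: pd.DataFrame,
    polygons: Mapping[str, object],
) -> pd.DataFrame:
    """Region, band, zone and nearest grid cell for every record; records
    without coordinates stay unassigned."""
    rows = []
    for _, r in records.iterrows():
        lat = r.get("latitude")
        lon = r.get("longitude")
        lat = None if pd.isna(lat) else float(lat)
        lon = None if pd.isna(lon) else float(lon)
        cell = nearest_cell(lat, lon, grid)
        rows.append({
            "record_id": r["record_id"],
            "region": None if cell is None else model.cell_regions[cell],
            "band": assign_band(lat),
            "zone": assign_zone(lat, lon, polygons),
            "cell_id": cell,
        })
    return pd.DataFrame(rows)
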