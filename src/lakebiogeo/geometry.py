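"""Great-circle geometry on the lake network.

All distances are haversine distances on a sphere of radius
``EARTH_RADIUS_KM`` (6,371.0 km, the common convention). Coordinates are
decimal degrees, WGS84 assumed. The sampled region (European lakes) never
crosses the antimeridian, so longitude spans >= 180 deg are rejected rather
than wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, ValidationError

EARTH_RADIUS_KM = 6371.0


def _as_latlon(lat, lon):
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValidationError("non-finite coordinates")
    if np.any(np.abs(lat) > 90.0):
        raise ValidationError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValidationError("longitude outside [-180, 180]")
    return lat, lon


def haversine_km(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between (lat1, lon1) and (lat2, lon2).

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lat1, lon1 = _as_latlon(lat1, lon1)
    lat2, lon2 = _as_latlon(lat2, lon2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    # clip guards tiny negative round-off before the sqrt
    d = 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if d.ndim == 0:
        return float(d)
    return d


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of great-circle distances (km) between lakes."""

    lake_ids: tuple
    values: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "_index", {k: i for i, k in enumerate(self.lake_ids)})

    def indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in ids], dtype=np.intp)
        except KeyError as e:
            raise ValidationError(f"unknown lake id {e.args[0]!r}") from None

    def submatrix(self, ids) -> np.ndarray:
        idx = self.indices(ids)
        return self.values[np.ix_(idx, idx)]


def distance_matrix(lake_ids, lats, lons) -> DistanceMatrix:
    """All-pairs haversine distances for a set of uniquely identified lakes."""
    lake_ids = tuple(lake_ids)
    if len(set(lake_ids)) != len(lake_ids):
        raise ValidationError("duplicate lake ids in distance matrix input")
    if len(lake_ids) == 0:
        raise ValidationError("need at least one lake")
    lat, lon = _as_latlon(lats, lons)
    if not (lat.shape == lon.shape == (len(lake_ids),)):
        raise ValidationError("lake_ids, lats, lons must have equal length")
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    d = np.atleast_2d(d)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(lake_ids, d)


def mean_pairwise_distance(ids, m: DistanceMatrix) -> float:
    """Mean over the n(n-1)/2 unordered lake pairs; requires n >= 2.

    Singleton taxa are excluded upstream (a taxon must occur in at least two
    lakes for its spatial extent to be defined).
    """
    ids = list(ids)
    n = len(ids)
    if n < 2:
        raise ValidationError("mean pairwise distance undefined for < 2 lakes")
    sub = m.submatrix(ids)
    return float(sub.sum() / (n * (n - 1)))


def mean_pairwise_from_indices(values: np.ndarray, idx: np.ndarray) -> float:
    """Same as :func:`mean_pairwise_distance` but on raw positions (hot path)."""
    n = len(idx)
    sub = values[np.ix_(idx, idx)]
    return float(sub.sum() / (n * (n - 1)))


@dataclass(frozen=True)
class BoundingBoxArea:
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    area_km2: float


def bounding_box_area_km2(lats, lons, radius: float = EARTH_RADIUS_KM) -> BoundingBoxArea:
    """Area of the latitude/longitude-aligned bounding box of a point set.

    Measured as geodesic width at the mid-latitude parallel times geodesic
    height along the mid-longitude meridian. For the continental extents in
    play (no antimeridian crossing, spans well under a hemisphere) alternative
    rectangle conventions agree within a few percent.
    """
    lat, lon = _as_latlon(lats, lons)
    lat, lon = np.atleast_1d(lat), np.atleast_1d(lon)
    if lat.size == 0:
        raise ValidationError("need at least one point")
    lat_min, lat_max = float(lat.min()), float(lat.max())
    lon_min, lon_max = float(lon.min()), float(lon.max())
    if lon_max - lon_min >= 180.0:
        raise ValidationError("longitude span >= 180 deg not supported (antimeridian)")
    mid_lat = (lat_min + lat_max) / 2.0
    mid_lon = (lon_min + lon_max) / 2.0
    width = haversine_km(mid_lat, lon_min, mid_lat, lon_max, radius=radius)
    height = haversine_km(lat_min, mid_lon, lat_max, mid_lon, radius=radius)
    return BoundingBoxArea(lat_min, lat_max, lon_min, lon_max, float(width * height))


def geometric_center(lats, lons):
    """Centroid of the unit-sphere embedding, re-projected to (lat, lon).

    Averaging 3-D unit vectors avoids longitude-wrap artifacts of naive
    lat/lon means. A perfectly antipodally balanced set has its centroid at
    the sphere's center, where the direction is undefined.
    """
    lat, lon = _as_latlon(lats, lons)
    lat, lon = np.atleast_1d(lat), np.atleast_1d(lon)
    if lat.size == 0:
        raise ValidationError("need at least one point")
    phi, lam = np.radians(lat), np.radians(lon)
    x = np.mean(np.cos(phi) * np.cos(lam))
    y = np.mean(np.cos(phi) * np.sin(lam))
    z = np.mean(np.sin(phi))
    norm = np.sqrt(x * x + y * y + z * z)
    if norm < 1e-12:
        raise DegenerateDataError("geometric center undefined: antipodally balanced points")
    return float(np.degrees(np.arcsin(z / norm))), float(np.degrees(np.arctan2(y, x)))
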