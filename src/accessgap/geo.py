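"""Spherical-earth geometry: great-circle distances, uniform areal sampling,
and neighbor queries.

All coordinates are WGS84-style latitude/longitude in decimal degrees, and all
distances are great-circle (haversine) kilometres on a sphere of mean radius
6371.0088 km.  At the scales this package works with (county discs of tens of
kilometres, national extents of thousands), the spherical model's deviation
from an ellipsoid (< 0.5%) is far below the placement noise of the simulation
itself, so no geodetic datum or projection machinery is used.

Neighbor queries (:func:`nearest_center`, :func:`centers_within_radius`) are
exact exhaustive searches, vectorised with numpy and chunked so that memory
stays bounded for large point sets.  Registries of diagnostic facilities are
small (order 10^2–10^3 centers), so exhaustive search is both fast and — unlike
approximate spatial indexes — exactly reproducible, with deterministic
smallest-id tie-breaking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "EARTH_RADIUS_KM",
    "EarthModel",
    "GeoPoint",
    "haversine_km",
    "haversine_km_arrays",
    "destination_point",
    "sample_uniform_disc",
    "nearest_center",
    "nearest_center_batch",
    "centers_within_radius",
]

#: IUGG mean earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: Largest disc radius (km) for which the locally-flat disc sampling law is
#: considered valid; beyond this the planar area/radius relation drifts from
#: the spherical-cap one by more than ~1%.
DISC_RADIUS_VALIDITY_KM = 500.0


def normalize_lon(lon: float) -> float:
    """Normalize a longitude in degrees to the half-open interval [-180, 180)."""
    return float((np.asarray(lon) + 180.0) % 360.0 - 180.0)


@dataclass(frozen=True)
class EarthModel:
    """Spherical earth with a configurable radius (km)."""

    radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if not self.radius_km > 0:
            raise ValueError(f"earth radius must be positive, got {self.radius_km}")


#: Default earth model shared by every distance computation in the package.
WGS84_SPHERE = EarthModel()


@dataclass(frozen=True)
class GeoPoint:
    """A latitude/longitude pair in decimal degrees.

    Latitude must lie in [-90, 90]; longitude is normalized on construction to
    [-180, 180), so points given as e.g. lon=190 and lon=-170 compare equal.
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        lat = float(self.lat)
        lon = float(self.lon)
        if not np.isfinite(lat) or not (-90.0 <= lat <= 90.0):
            raise ValueError(f"latitude {lat!r} outside [-90, 90]")
        if not np.isfinite(lon):
            raise ValueError(f"longitude {lon!r} is not finite")
        object.__setattr__(self, "lat", lat)
        object.__setattr__(self, "lon", normalize_lon(lon))


def haversine_km_arrays(
    lat1, lon1, lat2, lon2, earth: EarthModel = WGS84_SPHERE
) -> np.ndarray:
    """Vectorised great-circle distance (km) between degree coordinates.

    Inputs broadcast against each other like ordinary numpy operands.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # Clip guards tiny negative/>1 rounding before the sqrt/arcsin pair.
    return 2.0 * earth.radius_km * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def haversine_km(a: GeoPoint, b: GeoPoint, earth: EarthModel = WGS84_SPHERE) -> float:
    """Great-circle distance in km between two points.

    Symmetric in its arguments, zero iff the (normalized) points coincide, and
    never exceeds half the sphere's circumference.  Antimeridian-crossing pairs
    need no special casing: the haversine formula depends on the longitude
    difference only through its cosine-equivalent.
    """
    return float(haversine_km_arrays(a.lat, a.lon, b.lat, b.lon, earth))


def destination_point(
    lat, lon, bearing_rad, distance_km, earth: EarthModel = WGS84_SPHERE
) -> tuple[np.ndarray, np.ndarray]:
    """Point(s) reached by travelling ``distance_km`` along a great circle.

    Bearings are radians clockwise from north.  This is the exact spherical
    direct-geodesic formula, so ``haversine_km(start, dest)`` equals
    ``distance_km`` to floating-point precision — which is what makes the
    disc-sampling support bound exact.
    """
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    theta = np.asarray(bearing_rad, dtype=float)
    delta = np.asarray(distance_km, dtype=float) / earth.radius_km
    sin_lat2 = np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(theta)
    sin_lat2 = np.clip(sin_lat2, -1.0, 1.0)
    lat2 = np.arcsin(sin_lat2)
    lon2 = lon1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * sin_lat2,
    )
    lat2_deg = np.degrees(lat2)
    lon2_deg = (np.degrees(lon2) + 180.0) % 360.0 - 180.0
    return lat2_deg, lon2_deg


def sample_uniform_disc(
    center: GeoPoint,
    area_km2: float,
    n: int,
    rng: np.random.Generator,
    earth: EarthModel = WGS84_SPHERE,
) -> list[GeoPoint]:
    """Draw ``n`` points uniformly (per unit area) from a disc around ``center``.

    The disc radius is the equal-area radius R = sqrt(area / pi).  Radial
    distances follow the planar uniform-disc law r = R * sqrt(u) with a uniform
    bearing, and points are projected onto the sphere with the exact
    direct-geodesic formula, so every sample lies within great-circle distance
    R of the center.  The planar radial law is a locally-flat approximation,
    accurate to O((R / R_earth)^2); a warning is raised for R beyond
    ``DISC_RADIUS_VALIDITY_KM``.
    """
    if area_km2 < 0:
        raise ValueError(f"area_km2 must be non-negative, got {area_km2}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if n == 0:
        return []
    radius = float(np.sqrt(area_km2 / np.pi))
    if radius == 0.0:
        return [center] * n
    if radius > DISC_RADIUS_VALIDITY_KM:
        warnings.warn(
            f"disc radius {radius:.0f} km exceeds the {DISC_RADIUS_VALIDITY_KM:.0f} km "
            "validity cap of the locally-flat sampling law",
            RuntimeWarning,
            stacklevel=2,
        )
    r = radius * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * np.pi
    lats, lons = destination_point(center.lat, center.lon, theta, r, earth)
    return [GeoPoint(float(la), float(lo)) for la, lo in zip(lats, lons)]


def _center_arrays(centers: Sequence) -> tuple[list, np.ndarray, np.ndarray]:
    """Sort centers by id and return (sorted centers, lat array, lon array).

    Sorting by id up front means numpy's first-occurrence ``argmin`` realises
    the smallest-id tie-break for free.
    """
    if len(centers) == 0:
        raise ValueError("center list must be non-empty")
    ordered = sorted(centers, key=lambda c: c.center_id)
    lats = np.array([c.location.lat for c in ordered], dtype=float)
    lons = np.array([c.location.lon for c in ordered], dtype=float)
    return ordered, lats, lons


def nearest_center(point: GeoPoint, centers: Sequence) -> tuple[str, float]:
    """Identify the center minimising great-circle distance to ``point``.

    Returns ``(center_id, distance_km)``.  Exact ties are broken by the
    smallest center id so repeated runs are reproducible.
    """
    ordered, lats, lons = _center_arrays(centers)
    d = haversine_km_arrays(point.lat, point.lon, lats, lons)
    i = int(np.argmin(d))
    return ordered[i].center_id, float(d[i])


def nearest_center_batch(
    point_lats: np.ndarray,
    point_lons: np.ndarray,
    centers: Sequence,
    chunk_size: int = 2048,
) -> tuple[list[str], np.ndarray]:
    """Nearest center for many points at once.

    Returns ``(center_ids, distances_km)`` aligned with the input points.
    Chunked exhaustive search: exact, deterministic (smallest-id ties), and
    memory-bounded at ``chunk_size × n_centers`` floats.
    """
    ordered, clats, clons = _center_arrays(centers)
    point_lats = np.asarray(point_lats, dtype=float)
    point_lons = np.asarray(point_lons, dtype=float)
    n = point_lats.shape[0]
    ids: list[str] = []
    dists = np.empty(n, dtype=float)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        d = haversine_km_arrays(
            point_lats[start:stop, None], point_lons[start:stop, None], clats[None, :], clons[None, :]
        )
        idx = np.argmin(d, axis=1)
        dists[start:stop] = d[np.arange(stop - start), idx]
        ids.extend(ordered[i].center_id for i in idx)
    return ids, dists


def centers_within_radius(
    point: GeoPoint, centers: Sequence, radius_km: float
) -> list[str]:
    """Ids of all centers within ``radius_km`` of ``point`` (inclusive).

    The boundary is inclusive (d <= radius), so a center sitting exactly on a
    tier boundary counts as nearby.  Ids are returned in sorted order.
    """
    if radius_km < 0:
        raise ValueError(f"radius_km must be non-negative, got {radius_km}")
    ordered, lats, lons = _center_arrays(centers)
    d = haversine_km_arrays(point.lat, point.lon, lats, lons)
    return [ordered[i].center_id for i in np.flatnonzero(d <= radius_km)]


def distance_matrix_chunks(
    point_lats: np.ndarray,
    point_lons: np.ndarray,
    centers: Sequence,
    chunk_size: int = 2048,
) -> Iterator[tuple[int, int, list, np.ndarray]]:
    """Yield ``(start, stop, ordered_centers, distance block)`` over point chunks.

    Centers are id-sorted; each block has shape ``(stop - start, n_centers)``.
    Used by the tiered assignment rule, which needs the full per-point distance
    vector rather than just the minimum.
    """
    ordered, clats, clons = _center_arrays(centers)
    point_lats = np.asarray(point_lats, dtype=float)
    point_lons = np.asarray(point_lons, dtype=float)
    for start in range(0, point_lats.shape[0], chunk_size):
        stop = min(start + chunk_size, point_lats.shape[0])
        d = haversine_km_arrays(
            point_lats[start:stop, None], point_lons[start:stop, None], clats[None, :], clons[None, :]
        )
        yield start, stop, ordered, d
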