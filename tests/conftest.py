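import math

import numpy as np
import pytest

from accessgap import GeoPoint, ResourceCenter

EARTH_RADIUS_KM = 6371.0088


def haversine_scalar(lat1, lon1, lat2, lon2, radius=EARTH_RADIUS_KM):
    """Independent scalar haversine oracle built on the math module only."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2) - math.radians(lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * radius * math.asin(min(1.0, math.sqrt(h)))


def random_points(rng, n, lat_range=(-60, 60), lon_range=(-179, 179)):
    lats = rng.uniform(*lat_range, n)
    lons = rng.uniform(*lon_range, n)
    return [GeoPoint(float(a), float(b)) for a, b in zip(lats, lons)]


def make_centers(points, s=5, o=200):
    return [
        ResourceCenter(f"C{i:04d}", f"center {i}", p, s, o) for i, p in enumerate(points)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
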