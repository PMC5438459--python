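"""Stage 3: resource load, resource availability, gap classification, distance
summaries, and the availability heatmap grid.

**Resource load** of a center measures how well it can meet the demand placed
on it — a plain demand/supply ratio::

    RL_r = (N * p) / (s * o)

where ``N`` is the number of individuals assigned to (living near) the center,
``p`` the fraction of the population in need of a screening in a year
(default 0.195% = 6.5% of the population at a diagnosable age × 3% of those
needing a screening), ``s`` the number of specialists at the center, and ``o``
the yearly caseload of one specialist.  RL = 1 means demand exactly matches
capacity; RL = 6 means six-fold overburden.

**Resource availability** inverts the perspective to a location ``l``: each
center contributes according to how loaded it is and how far away it is::

    RA_l = sum_r  w(RL_r) * decay(d(r, l); z)

with, under the defaults, ``w(RL) = 1 / max(RL, 1)`` and
``decay(d) = 1 if d <= z else z / d``.  ``z`` is the distance an average
individual is willing to travel for the resource (default 30 km).  This form
has the defining boundary property: a single center at adequate load
(RL <= 1) within travel distance z gives RA exactly 1.  A **resource gap** is
a location with RA < 1 (strict).

The exact weight and decay shapes are genuinely underdetermined by the
verbal definition, so both are pluggable (``decay`` ∈ {capped_inverse,
exponential, hard_cutoff}; ``clamp_load_floor`` on/off); the defaults are the
minimal forms satisfying every stated property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .assignment import DEFAULT_TIERS_KM, ResourceCenter
from .geo import GeoPoint, haversine_km_arrays

__all__ = [
    "DEFAULT_SCREENING_FRACTION",
    "DEFAULT_TRAVEL_KM",
    "MetricParams",
    "LoadResult",
    "DistanceSummary",
    "AvailabilityGrid",
    "derive_screening_fraction",
    "resource_load",
    "resource_availability",
    "classify_gap",
    "summarize_distances",
    "availability_grid",
    "KM_PER_MILE",
]

#: Yearly screening-need fraction: 6.5% of the population at a diagnosable age,
#: of whom 3% need an autism screening.
DEFAULT_SCREENING_FRACTION = 0.065 * 0.03  # = 0.00195

#: Distance (km) an average individual is willing to travel for a diagnosis.
DEFAULT_TRAVEL_KM = 30.0

KM_PER_MILE = 1.0 / 0.621371

DECAY_KINDS = ("capped_inverse", "exponential", "hard_cutoff")


def derive_screening_fraction(age_fraction: float, need_fraction: float) -> float:
    """Fraction of the whole population needing a screening per year.

    The product of the fraction at a diagnosable age and the fraction of those
    needing a screening: 0.065 × 0.03 = 0.00195 under the defaults.
    """
    for name, value in (("age_fraction", age_fraction), ("need_fraction", need_fraction)):
        if not (0.0 < value < 1.0):
            raise ValueError(f"{name} must lie in (0, 1), got {value}")
    return age_fraction * need_fraction


@dataclass(frozen=True)
class MetricParams:
    """Tunables of the load/availability metrics.

    p
        fraction of the population in need of screening per year.
    z_km
        willingness-to-travel distance in km.
    decay
        distance down-weighting shape: ``capped_inverse`` (1 inside z, z/d
        beyond), ``exponential`` (1 inside z, exp(-(d-z)/z) beyond), or
        ``hard_cutoff`` (1 inside z, 0 beyond).
    clamp_load_floor
        if true (default), a center with spare capacity (RL < 1) contributes
        weight 1, not more — availability measures access, not surplus.
    tiers_km
        radius tiers for the tiered assignment rule, carried here so one
        object configures the whole metric stage.
    """

    p: float = DEFAULT_SCREENING_FRACTION
    z_km: float = DEFAULT_TRAVEL_KM
    decay: str = "capped_inverse"
    clamp_load_floor: bool = True
    tiers_km: tuple[float, ...] = DEFAULT_TIERS_KM

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if not self.z_km > 0:
            raise ValueError(f"z_km must be positive, got {self.z_km}")
        if self.decay not in DECAY_KINDS:
            raise ValueError(f"decay must be one of {DECAY_KINDS}, got {self.decay!r}")


@dataclass(frozen=True)
class LoadResult:
    """Resource load of one center: demand = N·p, capacity = s·o, rl = demand/capacity."""

    center_id: str
    n_assigned: int
    demand: float
    capacity: float
    rl: float


@dataclass(frozen=True)
class DistanceSummary:
    """Summary statistics of assigned distances (km): mean, sample SD, median,
    max, and the percentage of individuals within the travel distance z."""

    mean_km: float
    sd_km: float
    median_km: float
    max_km: float
    pct_within_z: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_km": self.mean_km,
            "sd_km": self.sd_km,
            "median_km": self.median_km,
            "max_km": self.max_km,
            "pct_within_z": self.pct_within_z,
            "n": self.n,
        }


def resource_load(
    center: ResourceCenter,
    n_assigned: int,
    p: float = DEFAULT_SCREENING_FRACTION,
    population_scale: float = 1.0,
) -> LoadResult:
    """Demand-to-capacity ratio RL = (N·p)/(s·o) for one center.

    Linear in ``n_assigned``; RL = 0 when nobody is assigned; RL > 1 means the
    center faces more yearly screening demand than it can serve.

    ``population_scale`` corrects for down-sampled populations: when the
    assigned individuals are a simulated fraction ``f`` of the real population,
    pass ``1/f`` so demand refers to the population the sample represents.
    """
    if n_assigned < 0:
        raise ValueError(f"n_assigned must be >= 0, got {n_assigned}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if not population_scale > 0:
        raise ValueError(f"population_scale must be positive, got {population_scale}")
    capacity = float(center.capacity)  # ResourceCenter guarantees s*o >= 1
    demand = n_assigned * population_scale * p
    return LoadResult(
        center_id=center.center_id,
        n_assigned=int(n_assigned),
        demand=demand,
        capacity=capacity,
        rl=demand / capacity,
    )


def _load_weights(rls: np.ndarray, clamp_load_floor: bool) -> np.ndarray:
    if clamp_load_floor:
        return 1.0 / np.maximum(rls, 1.0)
    if np.any(rls <= 0):
        raise ValueError(
            "unclamped load weighting (1/RL) is undefined for centers with RL = 0; "
            "use clamp_load_floor=True or assign demand to every center"
        )
    return 1.0 / rls


def _decay(distances: np.ndarray, z: float, kind: str) -> np.ndarray:
    d = np.asarray(distances, dtype=float)
    inside = d <= z
    if kind == "capped_inverse":
        with np.errstate(divide="ignore"):
            w = np.where(inside, 1.0, z / np.where(d > 0, d, np.inf))
    elif kind == "exponential":
        w = np.where(inside, 1.0, np.exp(-(d - z) / z))
    elif kind == "hard_cutoff":
        w = np.where(inside, 1.0, 0.0)
    else:  # pragma: no cover - guarded by MetricParams
        raise ValueError(f"unknown decay kind {kind!r}")
    return w


def _loads_arrays(
    loads: Sequence[tuple[ResourceCenter, LoadResult]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for center, load in loads:
        if center.center_id != load.center_id:
            raise ValueError(
                f"load result {load.center_id!r} does not match center {center.center_id!r}"
            )
    lats = np.array([c.location.lat for c, _ in loads], dtype=float)
    lons = np.array([c.location.lon for c, _ in loads], dtype=float)
    rls = np.array([l.rl for _, l in loads], dtype=float)
    return lats, lons, rls


def resource_availability(
    location: GeoPoint,
    loads: Sequence[tuple[ResourceCenter, LoadResult]],
    params: MetricParams = MetricParams(),
) -> float:
    """Availability RA at a location: load- and distance-weighted sum over centers.

    Under the defaults, one center with RL <= 1 within z km yields exactly 1;
    an empty center pool yields 0.  Adding a center never decreases RA;
    increasing a center's load or distance never increases it.
    """
    if not loads:
        return 0.0
    lats, lons, rls = _loads_arrays(loads)
    d = haversine_km_arrays(location.lat, location.lon, lats, lons)
    w = _load_weights(rls, params.clamp_load_floor) * _decay(d, params.z_km, params.decay)
    return float(np.sum(w))


def classify_gap(ra: float) -> bool:
    """True iff the location is a resource gap: availability strictly below 1."""
    if ra < 0:
        raise ValueError(f"availability must be >= 0, got {ra}")
    return ra < 1.0


def summarize_distances(
    assignment,
    z_km: float = DEFAULT_TRAVEL_KM,
    include_ids: Iterable[str] | None = None,
) -> DistanceSummary:
    """Summarise assigned distances: mean, sample SD (n−1), median (midpoint for
    even n), max, and the percentage within ``z_km`` (boundary inclusive).

    ``include_ids`` restricts the summary to a subset of individuals (e.g. the
    diagnosed); an empty selection is an error, not an all-NaN row.
    """
    df = assignment
    if include_ids is not None:
        wanted = set(include_ids)
        df = df[df["individual_id"].isin(wanted)]
    d = df["distance_km"].to_numpy(dtype=float)
    if d.size == 0:
        raise ValueError(
            "no distances to summarize: the assignment is empty after filtering "
            "(check the subset ids or the diagnosed flags)"
        )
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return DistanceSummary(
        mean_km=float(np.mean(d)),
        sd_km=sd,
        median_km=float(np.median(d)),
        max_km=float(np.max(d)),
        pct_within_z=float(100.0 * np.mean(d <= z_km)),
        n=int(d.size),
    )


@dataclass(frozen=True)
class AvailabilityGrid:
    """Availability evaluated on a regular latitude/longitude lattice.

    ``lats``/``lons`` are the axis coordinates; ``ra`` and ``gap`` are
    ``(len(lats), len(lons))`` arrays; ``gap[i, j]`` is ``ra[i, j] < 1``.
    """

    lats: np.ndarray
    lons: np.ndarray
    ra: np.ndarray
    gap: np.ndarray
    params: MetricParams = field(default_factory=MetricParams)

    def iter_points(self):
        """Yield ``(lat, lon, ra, gap)`` per lattice point, row-major."""
        for i, lat in enumerate(self.lats):
            for j, lon in enumerate(self.lons):
                yield float(lat), float(lon), float(self.ra[i, j]), bool(self.gap[i, j])


def _axis(lo: float, hi: float, step: float) -> np.ndarray:
    # ceil(span/step) + 1 points; the last may overshoot hi by < step
    n = int(math.ceil((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def availability_grid(
    bbox: tuple[float, float, float, float],
    resolution_deg: float,
    loads: Sequence[tuple[ResourceCenter, LoadResult]],
    params: MetricParams = MetricParams(),
) -> AvailabilityGrid:
    """Evaluate availability on a lat/lon lattice covering ``bbox``.

    ``bbox`` is ``(lat_min, lat_max, lon_min, lon_max)``.  Grid values equal
    point-wise :func:`resource_availability` calls exactly; gap flags follow
    :func:`classify_gap`.  The lattice is axis-aligned in degrees (no
    projection) — the natural input for heatmap rendering.
    """
    lat_min, lat_max, lon_min, lon_max = bbox
    if not (lat_min < lat_max and lon_min < lon_max):
        raise ValueError(f"bbox must be well-ordered (min < max), got {bbox}")
    if not resolution_deg > 0:
        raise ValueError(f"resolution_deg must be positive, got {resolution_deg}")
    lats = _axis(lat_min, lat_max, resolution_deg)
    lons = _axis(lon_min, lon_max, resolution_deg)

    if not loads:
        ra = np.zeros((lats.size, lons.size))
        return AvailabilityGrid(lats=lats, lons=lons, ra=ra, gap=ra < 1.0, params=params)

    clats, clons, rls = _loads_arrays(loads)
    wload = _load_weights(rls, params.clamp_load_floor)
    glat, glon = np.meshgrid(lats, lons, indexing="ij")
    flat_lat = glat.ravel()
    flat_lon = glon.ravel()
    ra = np.empty(flat_lat.size)
    chunk = 4096
    for start in range(0, flat_lat.size, chunk):
        stop = min(start + chunk, flat_lat.size)
        d = haversine_km_arrays(
            flat_lat[start:stop, None], flat_lon[start:stop, None], clats[None, :], clons[None, :]
        )
        ra[start:stop] = np.sum(wload[None, :] * _decay(d, params.z_km, params.decay), axis=1)
    ra = ra.reshape(lats.size, lons.size)
    return AvailabilityGrid(lats=lats, lons=lons, ra=ra, gap=ra < 1.0, params=params)
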