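"""Stage 2: map individuals to diagnostic centers.

Two assignment rules are provided:

* **nearest** — every individual goes to the center minimising great-circle
  distance (distance analyses: how far must people travel?).
* **tiered random** — every individual is assigned uniformly at random among
  the centers within the smallest of an ascending list of radii (default
  25, 100, 500, 3000 km) that contains at least one center (load analyses:
  how many people land on each center?).  Escalation is per individual: each
  person gets the smallest tier that works for *them*.

Assignments are plain pandas DataFrames with one row per individual, columns
``individual_id, center_id, distance_km, tier_km, fallback``.  ``tier_km`` is
NaN for the nearest rule; ``fallback`` marks individuals with no center inside
the largest tier, who are assigned to their nearest center and flagged rather
than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import GeoPoint, distance_matrix_chunks, nearest_center_batch
from .placement import Individual

__all__ = [
    "ResourceCenter",
    "DEFAULT_TIERS_KM",
    "ASSIGNMENT_COLUMNS",
    "assign_nearest",
    "assign_tiered_random",
    "per_center_counts",
]

#: Radius tiers (km) for the tiered-random rule.
DEFAULT_TIERS_KM = (25.0, 100.0, 500.0, 3000.0)

ASSIGNMENT_COLUMNS = ["individual_id", "center_id", "distance_km", "tier_km", "fallback"]


@dataclass(frozen=True)
class ResourceCenter:
    """Diagnostic facility: location, specialist head-count ``s``, and annual
    per-specialist caseload ``o``.  Its yearly service capacity is ``s * o``."""

    center_id: str
    name: str
    location: GeoPoint
    s: int = 5
    o: int = 200

    def __post_init__(self) -> None:
        if self.s < 1 or self.o < 1:
            raise ValueError(
                f"center {self.center_id}: s and o must be >= 1 (got s={self.s}, o={self.o})"
            )

    @property
    def capacity(self) -> int:
        """Individuals the center can attend per year."""
        return self.s * self.o


def _validate_inputs(individuals: list[Individual], centers: list[ResourceCenter]) -> None:
    if len(centers) == 0:
        raise ValueError("center list must be non-empty")
    ids = [ind.individual_id for ind in individuals]
    if len(set(ids)) != len(ids):
        raise ValueError("individual_id values must be unique")
    cids = [c.center_id for c in centers]
    if len(set(cids)) != len(cids):
        raise ValueError("center_id values must be unique")


def _coords(individuals: list[Individual]) -> tuple[np.ndarray, np.ndarray]:
    lats = np.array([ind.location.lat for ind in individuals], dtype=float)
    lons = np.array([ind.location.lon for ind in individuals], dtype=float)
    return lats, lons


def assign_nearest(
    individuals: list[Individual], centers: list[ResourceCenter]
) -> pd.DataFrame:
    """Assign every individual to its nearest center (ties: smallest center id)."""
    _validate_inputs(individuals, centers)
    if not individuals:
        return pd.DataFrame(columns=ASSIGNMENT_COLUMNS).astype(
            {"distance_km": float, "tier_km": float, "fallback": bool}
        )
    lats, lons = _coords(individuals)
    ids, dists = nearest_center_batch(lats, lons, centers)
    return pd.DataFrame(
        {
            "individual_id": [ind.individual_id for ind in individuals],
            "center_id": ids,
            "distance_km": dists,
            "tier_km": np.full(len(individuals), np.nan),
            "fallback": np.zeros(len(individuals), dtype=bool),
        }
    )


def assign_tiered_random(
    individuals: list[Individual],
    centers: list[ResourceCenter],
    tiers_km: tuple[float, ...] = DEFAULT_TIERS_KM,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign each individual uniformly at random among its in-tier centers.

    For each individual the smallest tier radius containing at least one
    center is found, and the assigned center is drawn uniformly from the
    centers within that radius (boundary inclusive).  If even the largest tier
    is empty the individual falls back to its nearest center with
    ``fallback=True``.
    """
    tiers = [float(t) for t in tiers_km]
    if not tiers or any(b <= a for a, b in zip(tiers, tiers[1:])) or tiers[0] < 0:
        raise ValueError(f"tiers must be a non-empty ascending list of radii, got {tiers_km}")
    _validate_inputs(individuals, centers)
    if rng is None:
        rng = np.random.default_rng()
    if not individuals:
        return pd.DataFrame(columns=ASSIGNMENT_COLUMNS).astype(
            {"distance_km": float, "tier_km": float, "fallback": bool}
        )

    lats, lons = _coords(individuals)
    out_center: list[str] = []
    out_dist = np.empty(len(individuals), dtype=float)
    out_tier = np.full(len(individuals), np.nan)
    out_fallback = np.zeros(len(individuals), dtype=bool)

    for start, stop, ordered, dblock in distance_matrix_chunks(lats, lons, centers):
        for row in range(dblock.shape[0]):
            d = dblock[row]
            chosen = -1
            for tier in tiers:
                candidates = np.flatnonzero(d <= tier)
                if candidates.size:
                    chosen = int(candidates[int(rng.integers(candidates.size))])
                    out_tier[start + row] = tier
                    break
            if chosen < 0:  # nothing within the largest tier: nearest + flag
                chosen = int(np.argmin(d))
                out_fallback[start + row] = True
            out_center.append(ordered[chosen].center_id)
            out_dist[start + row] = d[chosen]

    return pd.DataFrame(
        {
            "individual_id": [ind.individual_id for ind in individuals],
            "center_id": out_center,
            "distance_km": out_dist,
            "tier_km": out_tier,
            "fallback": out_fallback,
        }
    )


def per_center_counts(
    assignment: pd.DataFrame, centers: list[ResourceCenter] | None = None
) -> dict[str, int]:
    """Number of individuals assigned to each center (the ``N`` of the load ratio).

    When ``centers`` is given, centers with no assignees are included with
    count 0; otherwise only centers present in the assignment appear.
    """
    counts = assignment["center_id"].value_counts().to_dict()
    if centers is not None:
        counts = {c.center_id: int(counts.get(c.center_id, 0)) for c in centers}
    else:
        counts = {k: int(v) for k, v in counts.items()}
    return counts
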