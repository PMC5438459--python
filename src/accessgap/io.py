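"""Readers and writers for the pipeline's file interfaces.

All tables are UTF-8, comma-separated CSV with a mandatory header:

* regions:      ``region_id,name,lat,lon,land_area_km2,population``
* centers:      ``center_id,name,lat,lon,s,o``
* individuals:  ``individual_id,lat,lon,region_id,diagnosed``  (diagnosed 0/1)
* assignment:   ``individual_id,center_id,distance_km,tier_km,fallback``
* loads:        ``center_id,n_assigned,demand,capacity,rl``

Summaries and manifests are JSON; the availability grid is a GeoJSON
FeatureCollection of Point features ([lon, lat] coordinate order, RFC 7946)
with ``{"ra": ..., "gap": ...}`` properties, plus an optional flat CSV.

Readers validate every row and raise :class:`TableParseError` naming the file,
1-based data row, and field.  Writers are atomic per file (written to a
temporary sibling, then renamed), so a failing run never leaves a partial
output behind.  Floating-point output uses 6 significant digits.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .assignment import ASSIGNMENT_COLUMNS, ResourceCenter
from .geo import GeoPoint
from .metrics import AvailabilityGrid, DistanceSummary, LoadResult
from .placement import Individual, Region

__all__ = [
    "TableParseError",
    "read_regions",
    "read_centers",
    "read_individuals",
    "write_regions",
    "write_centers",
    "write_individuals",
    "write_assignment",
    "read_assignment",
    "write_loads",
    "write_summary_json",
    "write_grid_geojson",
    "write_grid_csv",
    "write_json",
    "atomic_write_text",
]

FLOAT_FORMAT = "%.6g"


class TableParseError(ValueError):
    """A malformed input table; message names file, row, and field."""

    def __init__(self, path, row: int | None, field: str | None, problem: str):
        self.path = str(path)
        self.row = row
        self.field = field
        where = self.path
        if row is not None:
            where += f", row {row}"
        if field is not None:
            where += f", field '{field}'"
        super().__init__(f"{where}: {problem}")


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableParseError(path, None, None, "file does not exist")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except Exception as exc:  # malformed CSV structure
        raise TableParseError(path, None, None, f"cannot parse CSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableParseError(path, None, None, f"missing column(s) {missing}; header must contain {columns}")
    return df


def _field(path, row: int, name: str, raw: str, convert: Callable, check=None, what: str = ""):
    try:
        value = convert(raw)
    except (TypeError, ValueError):
        raise TableParseError(path, row, name, f"cannot parse {raw!r} as {what or convert.__name__}") from None
    if check is not None and not check(value):
        raise TableParseError(path, row, name, f"value {value!r} out of range ({what})")
    return value


def _unique(path, series: pd.Series, name: str) -> None:
    dup = series[series.duplicated()]
    if not dup.empty:
        row = int(dup.index[0]) + 1
        raise TableParseError(path, row, name, f"duplicate id {dup.iloc[0]!r}")


def _point(path, row: int, lat_raw: str, lon_raw: str) -> GeoPoint:
    lat = _field(path, row, "lat", lat_raw, float, lambda v: -90 <= v <= 90, "latitude in [-90, 90]")
    lon = _field(path, row, "lon", lon_raw, float, np.isfinite, "finite longitude")
    return GeoPoint(lat, lon)


def read_regions(path) -> list[Region]:
    """Read and validate a region table CSV."""
    cols = ["region_id", "name", "lat", "lon", "land_area_km2", "population"]
    df = _read_table(path, cols)
    _unique(path, df["region_id"], "region_id")
    regions = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        point = _point(path, i, rec.lat, rec.lon)
        pop = _field(path, i, "population", rec.population, int, lambda v: v >= 0, "count >= 0")
        area = _field(path, i, "land_area_km2", rec.land_area_km2, float, np.isfinite, "finite area")
        if pop > 0 and area <= 0:
            raise TableParseError(path, i, "land_area_km2", f"must be positive when population > 0, got {area}")
        regions.append(Region(rec.region_id, rec.name, point, area, pop))
    return regions


def read_centers(path) -> list[ResourceCenter]:
    """Read and validate a center registry CSV (capacity s·o must be positive)."""
    cols = ["center_id", "name", "lat", "lon", "s", "o"]
    df = _read_table(path, cols)
    _unique(path, df["center_id"], "center_id")
    centers = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        point = _point(path, i, rec.lat, rec.lon)
        s = _field(path, i, "s", rec.s, int, lambda v: v >= 1, "specialists >= 1")
        o = _field(path, i, "o", rec.o, int, lambda v: v >= 1, "annual caseload >= 1")
        centers.append(ResourceCenter(rec.center_id, rec.name, point, s, o))
    return centers


def read_individuals(path) -> list[Individual]:
    """Read and validate an individual-location CSV (diagnosed coded 0/1)."""
    cols = ["individual_id", "lat", "lon", "region_id", "diagnosed"]
    df = _read_table(path, cols)
    _unique(path, df["individual_id"], "individual_id")
    individuals = []
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        point = _point(path, i, rec.lat, rec.lon)
        flag = _field(path, i, "diagnosed", rec.diagnosed, int, lambda v: v in (0, 1), "0 or 1")
        individuals.append(Individual(rec.individual_id, point, rec.region_id, bool(flag)))
    return individuals


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` atomically (temp sibling + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_df(path, df: pd.DataFrame) -> None:
    atomic_write_text(path, df.to_csv(index=False, float_format=FLOAT_FORMAT))


def write_regions(path, regions: Iterable[Region]) -> None:
    _write_df(
        path,
        pd.DataFrame(
            [
                {
                    "region_id": r.region_id,
                    "name": r.name,
                    "lat": r.centroid.lat,
                    "lon": r.centroid.lon,
                    "land_area_km2": r.land_area_km2,
                    "population": r.population,
                }
                for r in regions
            ],
            columns=["region_id", "name", "lat", "lon", "land_area_km2", "population"],
        ),
    )


def write_centers(path, centers: Iterable[ResourceCenter]) -> None:
    _write_df(
        path,
        pd.DataFrame(
            [
                {
                    "center_id": c.center_id,
                    "name": c.name,
                    "lat": c.location.lat,
                    "lon": c.location.lon,
                    "s": c.s,
                    "o": c.o,
                }
                for c in centers
            ],
            columns=["center_id", "name", "lat", "lon", "s", "o"],
        ),
    )


def write_individuals(path, individuals: Iterable[Individual]) -> None:
    _write_df(
        path,
        pd.DataFrame(
            [
                {
                    "individual_id": ind.individual_id,
                    "lat": ind.location.lat,
                    "lon": ind.location.lon,
                    "region_id": ind.region_id,
                    "diagnosed": int(ind.diagnosed),
                }
                for ind in individuals
            ],
            columns=["individual_id", "lat", "lon", "region_id", "diagnosed"],
        ),
    )


def write_assignment(path, assignment: pd.DataFrame) -> None:
    df = assignment.copy()
    df["fallback"] = df["fallback"].astype(int)
    _write_df(path, df[ASSIGNMENT_COLUMNS])


def read_assignment(path) -> pd.DataFrame:
    """Read an assignment CSV back into the canonical frame."""
    df = _read_table(path, ASSIGNMENT_COLUMNS)
    _unique(path, df["individual_id"], "individual_id")
    out = pd.DataFrame(
        {
            "individual_id": df["individual_id"],
            "center_id": df["center_id"],
            "distance_km": pd.to_numeric(df["distance_km"]),
            "tier_km": pd.to_numeric(df["tier_km"].replace("", np.nan)),
            "fallback": pd.to_numeric(df["fallback"]).astype(bool),
        }
    )
    if (out["distance_km"] < 0).any():
        row = int(out.index[out["distance_km"] < 0][0]) + 1
        raise TableParseError(path, row, "distance_km", "negative distance")
    return out


def write_loads(path, loads: Iterable[LoadResult]) -> None:
    _write_df(
        path,
        pd.DataFrame(
            [
                {
                    "center_id": l.center_id,
                    "n_assigned": l.n_assigned,
                    "demand": l.demand,
                    "capacity": l.capacity,
                    "rl": l.rl,
                }
                for l in loads
            ],
            columns=["center_id", "n_assigned", "demand", "capacity", "rl"],
        ),
    )


def _round_sig(x: float, sig: int = 6) -> float:
    return float(f"{x:.{sig}g}")


def write_json(path, payload: dict) -> None:
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_summary_json(path, summaries: dict[str, DistanceSummary]) -> None:
    """Write one or more named distance summaries (e.g. ``all``, ``diagnosed``)."""
    payload = {
        name: {k: (_round_sig(v) if isinstance(v, float) else v) for k, v in s.as_dict().items()}
        for name, s in summaries.items()
    }
    write_json(path, payload)


def write_grid_geojson(path, grid: AvailabilityGrid) -> None:
    """Availability grid as a GeoJSON FeatureCollection of Points.

    Coordinates are ``[lon, lat]`` per RFC 7946; each feature carries
    ``ra`` (rounded to 6 significant digits) and a boolean ``gap``.
    """
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [_round_sig(lon), _round_sig(lat)]},
            "properties": {"ra": _round_sig(ra), "gap": gap},
        }
        for lat, lon, ra, gap in grid.iter_points()
    ]
    atomic_write_text(
        path,
        json.dumps({"type": "FeatureCollection", "features": features}) + "\n",
    )


def write_grid_csv(path, grid: AvailabilityGrid) -> None:
    rows = [(lat, lon, ra, int(gap)) for lat, lon, ra, gap in grid.iter_points()]
    _write_df(path, pd.DataFrame(rows, columns=["lat", "lon", "ra", "gap"]))
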