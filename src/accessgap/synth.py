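"""Synthetic census-like scenarios: regions, center registries, and diagnosed
individuals with the statistical structure the analysis pipeline assumes.

Real inputs to this kind of analysis — a census extract of county populations
and land areas, a scraped registry of diagnostic centers, web-scraped locations
of diagnosed individuals — are rarely redistributable.  This module generates
stand-ins that reproduce the features the pipeline depends on:

* heavy-tailed region populations and areas (log-normal, matching the skew of
  real county-size distributions);
* centers placed preferentially where people are (population-weighted host
  region, uniform within the region's disc);
* an optional *diagnosis–distance bias*: a fraction ``q`` of diagnosed
  individuals live at an exponential distance from a random center, the rest
  are placed like the general population.  This is the simplest two-component
  mixture with a tunable effect size for the observation that people living
  closer to diagnostic services are more likely to be diagnosed; no generative
  form for the real phenomenon is claimed.

All randomness flows from one master seed; each stage (regions, centers,
individuals, placement) draws from an independently derived substream, so a
stage can be regenerated without rerunning the ones before it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .assignment import ResourceCenter
from .geo import GeoPoint, destination_point, sample_uniform_disc
from .placement import Individual, Region

__all__ = [
    "LogNormalModel",
    "IntModel",
    "ScenarioConfig",
    "stage_rng",
    "generate_regions",
    "generate_centers",
    "generate_individuals",
    "PRESETS",
    "get_preset",
    "Preset",
]

_STAGE_CODES = {"regions": 1, "centers": 2, "individuals": 3, "placement": 4, "assignment": 5}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one pipeline stage, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGE_CODES[stage]]))


@dataclass(frozen=True)
class LogNormalModel:
    """Log-normal distribution parameterised by its median and log-space sigma.

    ``sigma = 0`` degenerates to the constant ``median``.
    """

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.median > 0:
            raise ValueError(f"median must be positive, got {self.median}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            return np.full(n, float(self.median))
        return rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=n)


@dataclass(frozen=True)
class IntModel:
    """Small integer distribution for per-center staffing parameters.

    ``kind="constant"`` always returns ``lo``; ``kind="uniform"`` draws
    integers from [lo, hi] inclusive.
    """

    kind: Literal["constant", "uniform"] = "constant"
    lo: int = 1
    hi: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "uniform"):
            raise ValueError(f"unknown IntModel kind {self.kind!r}")
        if self.lo < 1:
            raise ValueError(f"lo must be >= 1, got {self.lo}")
        if self.kind == "uniform" and (self.hi is None or self.hi < self.lo):
            raise ValueError("uniform IntModel needs hi >= lo")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.lo, dtype=int)
        return rng.integers(self.lo, self.hi + 1, size=n)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic scenario.

    The bounding box is ``(lat_min, lat_max, lon_min, lon_max)`` in degrees and
    holds the region *centroids*; generated points can spill past it by at most
    one disc radius.  ``diagnosis_bias`` is the mixture weight ``q`` of the
    near-center component among diagnosed individuals and ``bias_scale_km`` its
    exponential distance scale.
    """

    n_regions: int = 300
    bbox: tuple[float, float, float, float] = (25.0, 49.0, -124.0, -67.0)
    population_model: LogNormalModel = field(default_factory=lambda: LogNormalModel(10_000, 1.0))
    area_model: LogNormalModel = field(default_factory=lambda: LogNormalModel(1_500, 0.8))
    n_centers: int = 80
    center_placement: Literal["population_weighted", "uniform"] = "population_weighted"
    s_model: IntModel = field(default_factory=lambda: IntModel("constant", 5))
    o_model: IntModel = field(default_factory=lambda: IntModel("constant", 200))
    diagnosis_bias: float = 0.0
    bias_scale_km: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_centers < 1:
            raise ValueError("n_regions and n_centers must be >= 1")
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if not (lat_min < lat_max and lon_min < lon_max):
            raise ValueError(f"bbox must be well-ordered (min < max), got {self.bbox}")
        if not (-90 <= lat_min and lat_max <= 90):
            raise ValueError(f"bbox latitudes outside [-90, 90]: {self.bbox}")
        if not (0.0 <= self.diagnosis_bias <= 1.0):
            raise ValueError(f"diagnosis_bias must lie in [0, 1], got {self.diagnosis_bias}")
        if not self.bias_scale_km > 0:
            raise ValueError(f"bias_scale_km must be positive, got {self.bias_scale_km}")

    # flat key/value form, so a scenario can live in a plain config file
    def to_flat_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "lat_min": self.bbox[0],
            "lat_max": self.bbox[1],
            "lon_min": self.bbox[2],
            "lon_max": self.bbox[3],
            "population_median": self.population_model.median,
            "population_sigma": self.population_model.sigma,
            "area_median": self.area_model.median,
            "area_sigma": self.area_model.sigma,
            "n_centers": self.n_centers,
            "center_placement": self.center_placement,
            "s_kind": self.s_model.kind,
            "s_lo": self.s_model.lo,
            "s_hi": self.s_model.hi,
            "o_kind": self.o_model.kind,
            "o_lo": self.o_model.lo,
            "o_hi": self.o_model.hi,
            "diagnosis_bias": self.diagnosis_bias,
            "bias_scale_km": self.bias_scale_km,
            "seed": self.seed,
        }

    @classmethod
    def from_flat_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(
            n_regions=int(d["n_regions"]),
            bbox=(float(d["lat_min"]), float(d["lat_max"]), float(d["lon_min"]), float(d["lon_max"])),
            population_model=LogNormalModel(float(d["population_median"]), float(d["population_sigma"])),
            area_model=LogNormalModel(float(d["area_median"]), float(d["area_sigma"])),
            n_centers=int(d["n_centers"]),
            center_placement=d["center_placement"],
            s_model=IntModel(d["s_kind"], int(d["s_lo"]), None if d.get("s_hi") in (None, "") else int(d["s_hi"])),
            o_model=IntModel(d["o_kind"], int(d["o_lo"]), None if d.get("o_hi") in (None, "") else int(d["o_hi"])),
            diagnosis_bias=float(d["diagnosis_bias"]),
            bias_scale_km=float(d["bias_scale_km"]),
            seed=int(d["seed"]),
        )


def generate_regions(config: ScenarioConfig) -> list[Region]:
    """Generate census-like regions: uniform centroids, log-normal populations/areas."""
    rng = stage_rng(config.seed, "regions")
    lat_min, lat_max, lon_min, lon_max = config.bbox
    lats = rng.uniform(lat_min, lat_max, config.n_regions)
    lons = rng.uniform(lon_min, lon_max, config.n_regions)
    pops = np.maximum(1, np.rint(config.population_model.draw(config.n_regions, rng))).astype(int)
    areas = config.area_model.draw(config.n_regions, rng)
    return [
        Region(
            region_id=f"R{i:04d}",
            name=f"Region {i}",
            centroid=GeoPoint(float(lats[i]), float(lons[i])),
            land_area_km2=float(areas[i]),
            population=int(pops[i]),
        )
        for i in range(config.n_regions)
    ]


def generate_centers(regions: list[Region], config: ScenarioConfig) -> list[ResourceCenter]:
    """Generate a center registry over the given regions.

    Under ``population_weighted`` placement each center's host region is drawn
    with probability proportional to region population (so centers concentrate
    where people are); under ``uniform`` every region is equally likely.  Each
    center is then placed uniformly within its host region's disc, and staffing
    ``s``/``o`` drawn from the configured distributions.
    """
    if not regions:
        raise ValueError("region list must be non-empty")
    rng = stage_rng(config.seed, "centers")
    if config.center_placement == "population_weighted":
        weights = np.array([r.population for r in regions], dtype=float)
        if weights.sum() <= 0:
            raise ValueError("population_weighted placement needs total population > 0")
        probs = weights / weights.sum()
    elif config.center_placement == "uniform":
        probs = np.full(len(regions), 1.0 / len(regions))
    else:
        raise ValueError(f"unknown center_placement {config.center_placement!r}")
    hosts = rng.choice(len(regions), size=config.n_centers, p=probs)
    s_vals = config.s_model.draw(config.n_centers, rng)
    o_vals = config.o_model.draw(config.n_centers, rng)
    centers = []
    for i, host in enumerate(hosts):
        region = regions[int(host)]
        pt = sample_uniform_disc(region.centroid, region.land_area_km2, 1, rng)[0]
        centers.append(
            ResourceCenter(
                center_id=f"C{i:04d}",
                name=f"Center {i}",
                location=pt,
                s=int(s_vals[i]),
                o=int(o_vals[i]),
            )
        )
    return centers


def generate_individuals(
    regions: list[Region],
    centers: list[ResourceCenter],
    config: ScenarioConfig,
    n_diagnosed: int,
) -> list[Individual]:
    """Generate diagnosed individuals under the diagnosis–distance bias mixture.

    With probability ``q = config.diagnosis_bias`` an individual lives at an
    Exponential(``bias_scale_km``) radial distance, uniform bearing, from a
    uniformly chosen center; with probability 1 − q they are placed like the
    general population (population-weighted region, uniform within its disc).
    ``q = 0`` therefore makes the diagnosed spatially indistinguishable from
    everyone else; ``q = 1`` pins them to center neighbourhoods.
    """
    if not regions or not centers:
        raise ValueError("regions and centers must be non-empty")
    if n_diagnosed < 0:
        raise ValueError(f"n_diagnosed must be >= 0, got {n_diagnosed}")
    rng = stage_rng(config.seed, "individuals")
    weights = np.array([r.population for r in regions], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("cannot place individuals: total population is 0")
    probs = weights / total

    near = rng.random(n_diagnosed) < config.diagnosis_bias
    out: list[Individual] = []
    for i in range(n_diagnosed):
        if near[i]:
            center = centers[int(rng.integers(len(centers)))]
            r = float(rng.exponential(config.bias_scale_km))
            theta = float(rng.random() * 2.0 * np.pi)
            la, lo = destination_point(center.location.lat, center.location.lon, theta, r)
            pt = GeoPoint(float(la), float(lo))
            region_id = ""
        else:
            region = regions[int(rng.choice(len(regions), p=probs))]
            pt = sample_uniform_disc(region.centroid, region.land_area_km2, 1, rng)[0]
            region_id = region.region_id
        out.append(
            Individual(
                individual_id=f"asd{i:06d}",
                location=pt,
                region_id=region_id,
                diagnosed=True,
            )
        )
    return out


@dataclass(frozen=True)
class Preset:
    """A named scenario plus the pipeline knobs that go with it."""

    config: ScenarioConfig
    sampling_fraction: float
    n_diagnosed: int
    description: str = ""

    def with_seed(self, seed: int) -> "Preset":
        return replace(self, config=replace(self.config, seed=int(seed)))


PRESETS: dict[str, Preset] = {
    # Continental-US-like extent, ~50k simulated individuals, runs in seconds.
    "us_like_small": Preset(
        config=ScenarioConfig(),
        sampling_fraction=0.01,
        n_diagnosed=0,
        description="300 log-normal regions over a continental-scale bbox, 80 "
        "population-weighted centers, ~50,000 simulated individuals (1% sample).",
    ),
    # Same geography with a strong diagnosis-distance bias to detect downstream.
    "biased_diagnosis": Preset(
        config=ScenarioConfig(diagnosis_bias=0.8, bias_scale_km=10.0),
        sampling_fraction=0.01,
        n_diagnosed=2000,
        description="us_like_small plus 2000 diagnosed individuals, 80% of whom "
        "live within an exponential(10 km) distance of a center.",
    ),
    # Small instance for smoke tests and examples.
    "demo_tiny": Preset(
        config=ScenarioConfig(
            n_regions=40,
            n_centers=8,
            population_model=LogNormalModel(1_000, 1.0),
            area_model=LogNormalModel(1_200, 0.8),
        ),
        sampling_fraction=0.05,
        n_diagnosed=200,
        description="40 regions, 8 centers, ~3,000 individuals; for quick runs.",
    ),
}


def get_preset(name: str, seed: int | None = None) -> Preset:
    """Look up a preset by name, optionally re-seeding it."""
    try:
        preset = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return preset if seed is None else preset.with_seed(seed)
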