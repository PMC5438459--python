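# Methods

## Model overview

`accessgap` models access to diagnostic services in three stages.

**1. Population placement.** Each region of a census-style table is reduced to
an equal-area disc around its centroid (radius `R = sqrt(area/π)`), and
`round(population × f)` individuals are placed uniformly per unit area within
it, where `f` is a sampling fraction in (0, 1] (`f = 1` simulates everyone;
rounding is half-to-even so totals are platform-reproducible). Uniform
placement ignores within-region clustering around towns; since people actually
cluster where services are, this tends to *overstate* distances somewhat. That
is an accepted property of the design, not a bug to calibrate away.

**2. Assignment.** Either *nearest* — each individual to the center minimising
great-circle distance (ties broken by smallest center id) — or
*tiered-random*: for each individual the smallest radius among an ascending
tier list (default 25, 100, 500, 3000 km) that contains at least one center is
found, and the assigned center is drawn uniformly among the centers within it
(boundary inclusive). Tier escalation is per individual. The nearest rule
answers "how far is care?"; the tiered rule spreads demand across plausible
catchments for the load computation. Synthetic geographies cannot guarantee a
center within the largest tier, so individuals beyond it fall back to their
nearest center and are flagged (`fallback=1`), never dropped.

**3. Metrics.**

- Resource load: `RL_r = (N_r · p) / (s_r · o_r)` with `N_r` the assigned
  count. When individuals were simulated at fraction `f`, demand is rescaled
  by `1/f` so RL refers to the population the sample represents; otherwise a
  1% sample would deflate every load a hundred-fold.
- Resource availability at location l:
  `RA_l = Σ_r w(RL_r) · decay(d(r,l))` with defaults
  `w(RL) = 1/max(RL, 1)` and `decay(d) = 1 if d ≤ z else z/d`.
- Gap: `RA < 1` (strict; RA = 1 is adequate).
- Distance summaries: mean, sample SD (n−1), median (midpoint for even n),
  max, and `100 × fraction(d ≤ z)`.
- Availability grid: RA evaluated on an axis-aligned lat/lon lattice with
  `ceil(span/step) + 1` points per axis (the last row/column may overshoot the
  bbox by less than one step). No map projection is involved; the lattice is
  in degrees because that is what heatmap renderers consume.

## The availability form and its alternatives

The verbal definition of availability — a sum over resources, each
down-weighted by load and distance, equal to at least 1 when one adequate
resource is within the travel distance — does not pin down the algebra. The
implemented default is the minimal form with all the stated properties:
monotone non-decreasing when centers are added, non-increasing in any RL or
distance, and exactly 1 for a single RL ≤ 1 center within z. Both pieces are
pluggable:

- `decay`: `capped_inverse` (default, 1 inside z, z/d beyond), `exponential`
  (1 inside z, `exp(-(d-z)/z)` beyond), `hard_cutoff` (0 beyond z). All three
  agree inside z and at d = 0 (no division by zero anywhere).
- `clamp_load_floor`: with the default `True`, a center with spare capacity
  (RL < 1) contributes at most 1 — availability measures *access*, not
  surplus capacity. The unclamped variant `1/RL` rewards under-used centers;
  it is selectable but undefined at RL = 0, which raises an input error
  rather than returning infinity.

## Geometry

Earth is a sphere of radius 6371.0088 km; all distances are haversine
great-circle distances (symmetric, bounded by half the circumference, correct
across the antimeridian with no special casing). At county-to-continental
scales, sphere-vs-ellipsoid error (< 0.5%) is negligible against placement
noise. Disc sampling draws the planar uniform-disc radial law `r = R·sqrt(u)`
with a uniform bearing and projects with the exact spherical direct-geodesic
formula, so the support bound (every sample within R of the centroid) holds to
float precision; the planar density law drifts from the spherical-cap one by
O((R/R_earth)²), and a warning is issued for discs beyond R = 500 km, far
above any county-scale radius.

Neighbor queries are exact chunked exhaustive searches rather than a spatial
index: center registries are small (order 10²–10³), a vectorised distance
block is fast at 10⁵ × 10³ scale, and exhaustive argmin over id-sorted centers
makes the smallest-id tie-break exact and runs bit-reproducible — properties a
KD-tree on a chord-distance embedding only provides with extra tie-handling
machinery.

## Synthetic scenarios

The generator emulates the statistical structure of real inputs, not any real
geography:

- Region populations and land areas are log-normal (parameterised by median
  and log-sigma), matching the heavy right skew of county-size distributions.
  `sigma = 0` degenerates to constants for tests.
- Centers pick a host region with probability proportional to population
  (facilities concentrate where people are), then a uniform position within
  the host disc. Staffing `s`, `o` come from configurable integer
  distributions, default constants 5 and 200.
- Diagnosed individuals follow a two-component mixture: with probability `q`
  an exponential(`bias_scale_km`) radial displacement from a uniformly chosen
  center, otherwise placement like the general population. This is the
  simplest generative model with a tunable effect size for the observation
  that people near services are likelier to be diagnosed; `q` and the scale
  are free parameters, not calibrated claims — real-data effect sizes are
  unknown.
- One master seed; each stage (regions, centers, individuals, placement,
  assignment) derives an independent substream from it, so stages can be
  regenerated in isolation and pipelines are byte-reproducible end to end.

Preset problem sizes are chosen so the full pipeline and test suite run on a
single CPU in seconds: `us_like_small` (300 regions over a continental bbox,
80 centers, 1% sample ≈ 50,000 individuals), `biased_diagnosis` (the same
plus 2,000 diagnosed at q = 0.8, scale 10 km), `demo_tiny` (40 regions,
8 centers, ≈ 3,000 individuals).

What passing tests on these scenarios shows: the pipeline's algebra,
conservation laws, determinism, and its ability to recover a planted
distance-to-diagnosis bias. What it does not show: agreement with any real
country's distances or load distribution — those depend on real registries
and census tables, which users must supply as CSV.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `p` | 0.00195 | fraction of population needing a screening per year (= 0.065 × 0.03) |
| `z_km` | 30 | willingness-to-travel distance, km |
| `s`, `o` | 5, 200 | specialists per center; yearly caseload per specialist |
| tiers | 25, 100, 500, 3000 km | catchment radii for tiered-random assignment |
| `decay` | capped_inverse | distance down-weighting beyond z |
| `clamp_load_floor` | true | spare capacity contributes at most 1 |
| grid resolution | 0.25° | availability lattice step |
| `sampling_fraction` | 1.0 | simulated fraction of each region's population |

## Numerical and interface choices

- Radius comparisons are inclusive (`d ≤ radius`), everywhere: tier
  membership, `% within z`, within-radius queries.
- Sample SD uses n−1; a single observation reports SD 0.
- CSV schemas are fixed and validated row by row; errors name file, row, and
  field. All writes are atomic (temp file + rename), so a failed run leaves
  no partial bundle.
- Floating output is printed at 6 significant digits; GeoJSON uses
  `[lon, lat]` coordinate order per RFC 7946.
- The manifest records config, seed, version, and row counts — but no
  timestamps, so identical config + seed give byte-identical bundles.
- Kilometres are the computation unit throughout; miles, where wanted, are a
  display conversion (× 0.621371).

## Known limitations

- Equal-area discs ignore region shape and shared borders; individuals of
  adjacent regions can overlap in space.
- No road network, travel time, capacity constraint, or willingness to travel
  farther for higher-quality care; assignment is purely geometric.
- The tiered rule's uniform choice among in-tier centers is unweighted by
  distance or capacity.
- The availability grid is unnormalised by local population; it maps access,
  not person-weighted unmet demand.
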