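"""Load, availability, gap, and distance-summary metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from accessgap import (
    GeoPoint,
    MetricParams,
    ResourceCenter,
    availability_grid,
    classify_gap,
    derive_screening_fraction,
    resource_availability,
    resource_load,
    summarize_distances,
)


def center_at(lat, lon, cid="C0", s=5, o=200):
    return ResourceCenter(cid, cid, GeoPoint(lat, lon), s, o)


def loaded_center(distance_km, rl, cid="C0"):
    """A center ``distance_km`` east of the origin along the equator with a
    load record carrying exactly the requested RL."""
    from accessgap import LoadResult

    from accessgap import EARTH_RADIUS_KM

    lon = distance_km / (2 * math.pi * EARTH_RADIUS_KM / 360)  # equatorial arc per degree
    c = center_at(0.0, lon, cid)
    load = LoadResult(cid, int(round(rl * c.capacity / 0.00195)), rl * c.capacity, float(c.capacity), rl)
    return c, load


class TestResourceLoad:
    def test_demand_equal_capacity_gives_unit_load(self):
        # 512,821 x 0.195% ~= 1000 = 5 specialists x 200 yearly cases
        res = resource_load(center_at(0, 0), 512_821, p=0.00195)
        assert res.rl == pytest.approx(1.0, rel=1e-3)
        assert res.demand == pytest.approx(res.capacity, rel=1e-3)

    def test_sixfold_demand_gives_load_six(self):
        res = resource_load(center_at(0, 0), 3_076_923, p=0.00195)
        assert res.rl == pytest.approx(6.0, rel=1e-3)

    def test_zero_assignment_zero_load(self):
        assert resource_load(center_at(0, 0), 0).rl == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.integers(min_value=0, max_value=10**7), st.integers(min_value=1, max_value=20))
    def test_linearity_in_assigned_count(self, n, k):
        base = resource_load(center_at(0, 0), n).rl
        scaled = resource_load(center_at(0, 0), k * n).rl
        assert scaled == pytest.approx(k * base, rel=1e-12, abs=1e-15)

    def test_population_scale_corrects_downsampled_counts(self):
        # a 1% sample with scale 100 gives the same RL as the full population
        full = resource_load(center_at(0, 0), 512_800, p=0.00195)
        sampled = resource_load(center_at(0, 0), 5_128, p=0.00195, population_scale=100.0)
        assert sampled.rl == pytest.approx(full.rl, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            resource_load(center_at(0, 0), -1)
        with pytest.raises(ValueError):
            resource_load(center_at(0, 0), 10, p=0.0)
        with pytest.raises(ValueError):
            ResourceCenter("x", "x", GeoPoint(0, 0), 0, 200)  # capacity would be 0


class TestScreeningFraction:
    @pytest.mark.parametrize(
        ("age", "need", "expected"),
        [(0.065, 0.03, 0.00195), (0.999, 0.999, 0.998001), (0.5, 0.5, 0.25)],
    )
    def test_product(self, age, need, expected):
        assert derive_screening_fraction(age, need) == pytest.approx(expected, rel=1e-12)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            derive_screening_fraction(0.0, 0.5)
        with pytest.raises(ValueError):
            derive_screening_fraction(0.5, 1.0)


class TestResourceAvailability:
    def test_one_adequate_center_within_z_gives_exactly_one(self):
        pair = loaded_center(10.0, 1.0)
        ra = resource_availability(GeoPoint(0, 0), [pair])
        assert ra == pytest.approx(1.0, abs=1e-12)

    def test_spare_capacity_is_clamped_to_one(self):
        pair = loaded_center(10.0, 0.2)  # RL < 1 still contributes exactly 1
        assert resource_availability(GeoPoint(0, 0), [pair]) == pytest.approx(1.0, abs=1e-12)

    def test_no_centers_gives_zero(self):
        assert resource_availability(GeoPoint(0, 0), []) == 0.0

    def test_distance_and_load_halve_availability(self):
        # RL=1 at 60 km with z=30: decay z/d = 0.5; RL=2 at 10 km: weight 1/2
        far = loaded_center(60.0, 1.0)
        ra_far = resource_availability(GeoPoint(0, 0), [far])
        assert ra_far == pytest.approx(0.5, rel=1e-6)
        overloaded = loaded_center(10.0, 2.0)
        ra_over = resource_availability(GeoPoint(0, 0), [overloaded])
        assert ra_over == pytest.approx(0.5, rel=1e-6)

    def test_adding_a_center_never_decreases_ra(self, rng):
        loc = GeoPoint(0, 0)
        pool = []
        previous = 0.0
        for k in range(8):
            pool.append(loaded_center(float(rng.uniform(1, 500)), float(rng.uniform(0.2, 30)), f"C{k}"))
            ra = resource_availability(loc, pool)
            assert ra >= previous - 1e-12
            previous = ra

    def test_monotone_in_load_and_distance(self):
        loc = GeoPoint(0, 0)
        for rl_lo, rl_hi in [(1.0, 2.0), (3.0, 10.0)]:
            assert resource_availability(loc, [loaded_center(50.0, rl_lo)]) >= resource_availability(
                loc, [loaded_center(50.0, rl_hi)]
            )
        for d_lo, d_hi in [(5.0, 20.0), (40.0, 400.0)]:
            assert resource_availability(loc, [loaded_center(d_lo, 1.0)]) >= resource_availability(
                loc, [loaded_center(d_hi, 1.0)]
            )

    @pytest.mark.parametrize("decay", ["capped_inverse", "exponential", "hard_cutoff"])
    def test_all_decays_agree_inside_z(self, decay):
        params = MetricParams(decay=decay)
        ra = resource_availability(GeoPoint(0, 0), [loaded_center(25.0, 1.0)], params)
        assert ra == pytest.approx(1.0, abs=1e-12)

    def test_decay_variants_beyond_z(self):
        pair = loaded_center(60.0, 1.0)
        loc = GeoPoint(0, 0)
        assert resource_availability(loc, [pair], MetricParams(decay="hard_cutoff")) == 0.0
        expo = resource_availability(loc, [pair], MetricParams(decay="exponential"))
        assert expo == pytest.approx(math.exp(-1.0), rel=1e-6)

    def test_unclamped_weighting_rewards_spare_capacity(self):
        pair = loaded_center(10.0, 0.5)
        ra = resource_availability(GeoPoint(0, 0), [pair], MetricParams(clamp_load_floor=False))
        assert ra == pytest.approx(2.0, rel=1e-6)
        zero = loaded_center(10.0, 0.0)
        with pytest.raises(ValueError):
            resource_availability(GeoPoint(0, 0), [zero], MetricParams(clamp_load_floor=False))

    def test_mismatched_load_result_errors(self):
        c, load = loaded_center(10.0, 1.0)
        other = center_at(1, 1, "OTHER")
        with pytest.raises(ValueError):
            resource_availability(GeoPoint(0, 0), [(other, load)])


class TestClassifyGap:
    @pytest.mark.parametrize(("ra", "expected"), [(1.0, False), (0.999, True), (0.0, True), (5.0, False)])
    def test_strict_threshold(self, ra, expected):
        assert classify_gap(ra) is expected

    def test_negative_availability_rejected(self):
        with pytest.raises(ValueError):
            classify_gap(-0.1)


class TestSummarizeDistances:
    @staticmethod
    def frame(distances, ids=None):
        n = len(distances)
        return pd.DataFrame(
            {
                "individual_id": ids or [f"i{k}" for k in range(n)],
                "center_id": ["C0"] * n,
                "distance_km": distances,
                "tier_km": [np.nan] * n,
                "fallback": [False] * n,
            }
        )

    def test_all_zero_distances(self):
        s = summarize_distances(self.frame([0.0, 0.0, 0.0]), z_km=30)
        assert (s.mean_km, s.sd_km, s.median_km, s.max_km, s.pct_within_z) == (0, 0, 0, 0, 100)

    def test_hand_computed_example(self):
        s = summarize_distances(self.frame([10.0, 20.0, 30.0, 40.0]), z_km=30)
        assert s.mean_km == pytest.approx(25.0)
        assert s.median_km == pytest.approx(25.0)  # midpoint convention for even n
        assert s.max_km == pytest.approx(40.0)
        assert s.pct_within_z == pytest.approx(75.0)  # 30 <= z inclusive
        assert s.sd_km == pytest.approx(math.sqrt(500.0 / 3.0), rel=1e-12)

    def test_single_observation(self):
        s = summarize_distances(self.frame([7.0]), z_km=30)
        assert (s.mean_km, s.median_km, s.max_km, s.sd_km, s.n) == (7.0, 7.0, 7.0, 0.0, 1)

    def test_subset_filter(self):
        df = self.frame([5.0, 50.0, 500.0])
        s = summarize_distances(df, z_km=30, include_ids=["i0", "i2"])
        assert s.n == 2
        assert s.mean_km == pytest.approx(252.5)

    def test_empty_after_filter_errors(self):
        with pytest.raises(ValueError, match="empty after filtering"):
            summarize_distances(self.frame([1.0]), include_ids=["missing"])

    def test_agrees_with_independent_recomputation(self, rng):
        # streaming (Welford) oracle on 1e5 random values
        d = rng.gamma(2.0, 60.0, 100_000)
        s = summarize_distances(self.frame(list(d)), z_km=30)
        count, mean, m2, mx, within = 0, 0.0, 0.0, 0.0, 0
        for x in d:
            count += 1
            delta = x - mean
            mean += delta / count
            m2 += delta * (x - mean)
            mx = max(mx, x)
            within += x <= 30
        assert s.mean_km == pytest.approx(mean, rel=1e-9)
        assert s.sd_km == pytest.approx(math.sqrt(m2 / (count - 1)), rel=1e-9)
        assert s.max_km == pytest.approx(mx, rel=1e-12)
        assert s.pct_within_z == pytest.approx(100.0 * within / count, rel=1e-9)
        assert s.median_km == pytest.approx(float(np.sort(d)[49999:50001].mean()), rel=1e-9)


class TestAvailabilityGrid:
    BBOX = (-1.0, 1.0, -1.0, 1.0)

    def test_no_centers_all_gaps(self):
        grid = availability_grid(self.BBOX, 0.5, [])
        assert grid.ra.shape == (5, 5)
        assert np.all(grid.ra == 0.0)
        assert np.all(grid.gap)

    def test_grid_dimensions(self):
        grid = availability_grid((0.0, 1.0, 0.0, 2.3), 0.25, [])
        assert grid.lats.size == math.ceil(1.0 / 0.25) + 1
        assert grid.lons.size == math.ceil(2.3 / 0.25) + 1

    def test_single_adequate_center_fills_z_disc(self):
        pair = loaded_center(0.0, 1.0)
        grid = availability_grid(self.BBOX, 0.1, [pair])
        lat_idx = np.argmin(np.abs(grid.lats - 0.0))
        lon_idx = np.argmin(np.abs(grid.lons - 0.0))
        assert grid.ra[lat_idx, lon_idx] == pytest.approx(1.0, abs=1e-12)
        assert not grid.gap[lat_idx, lon_idx]

    def test_grid_matches_pointwise_calls(self, rng):
        pairs = [loaded_center(float(rng.uniform(5, 200)), float(rng.uniform(0.5, 10)), f"C{k}") for k in range(4)]
        grid = availability_grid(self.BBOX, 0.4, pairs)
        for lat, lon, ra, gap in grid.iter_points():
            direct = resource_availability(GeoPoint(lat, lon), pairs)
            assert ra == pytest.approx(direct, rel=1e-12, abs=1e-12)
            assert gap == classify_gap(direct)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            availability_grid((1.0, -1.0, 0.0, 1.0), 0.5, [])
        with pytest.raises(ValueError):
            availability_grid(self.BBOX, 0.0, [])
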