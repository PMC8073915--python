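"""Departure identification, crossing/circumnavigation geometry, covariates."""

from datetime import timedelta

import numpy as np
import pytest
from shapely.geometry import box

from _oracles import lattice_path_km
from conftest import make_segment, utc
from nightcross import (
    GPSFix,
    LandWaterMask,
    circumnavigation_distance,
    classify_surface,
    identify_departures,
    scale_center,
    water_land_ratio,
)
from nightcross.crossing import (
    DepartureExclusion,
    barrier_extent_km,
    build_departure_table,
    crossing_distance,
)
from nightcross.geo import destination_point, geodesic_km


@pytest.fixture
def band_mask():
    """An east-west water band crossed due north, synthetic-world style."""
    return LandWaterMask({"sea": box(-82.0, 8.0, -62.0, 17.0)})


def _track(points, t0=None, bird="B1"):
    """Fixes every 12 h through the given (lat, lon) points."""
    t0 = t0 or utc(2018, 3, 10, 11)
    slots = ["0600", "1800"]
    return [
        GPSFix(bird, t0 + timedelta(hours=12 * i), la, lo, slot=slots[i % 2])
        for i, (la, lo) in enumerate(points)
    ]


def _segments(fixes, mask):
    from nightcross import TagSchedule, build_segments

    sched = TagSchedule(fixes[0].bird_id, -5.0, ("0600", "1800"))
    segs = build_segments(fixes, sched)
    for s in segs:
        classify_surface(s, mask, step_km=5.0)
    return segs


class TestRatioAndScaling:
    def test_reported_gulf_shortcut_ratio(self):
        assert water_land_ratio(871.0, 937.0) == pytest.approx(0.9296, abs=1e-4)

    def test_equal_distances_give_unity(self):
        assert water_land_ratio(500.0, 500.0) == 1.0
        assert water_land_ratio(500.0, 1000.0) == 0.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            water_land_ratio(0.0, 100.0)
        with pytest.raises(ValueError):
            water_land_ratio(100.0, -1.0)

    def test_scale_center_two_points(self):
        out = scale_center([1.0, 3.0])
        assert out == pytest.approx([-0.7071, 0.7071], abs=1e-4)

    def test_scale_center_moments(self):
        out = scale_center([2.0, 4.0, 6.0, 8.0])
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_scale_center_idempotent_on_standardized(self):
        x = scale_center(np.random.default_rng(0).normal(size=50))
        assert np.allclose(scale_center(x), x, atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            scale_center([2.0, 2.0, 2.0])


class TestCircumnavigation:
    def test_unobstructed_equals_geodesic(self, band_mask):
        a, b = (2.0, -86.0), (6.0, -86.0)
        d = circumnavigation_distance(a, b, band_mask)
        assert d == pytest.approx(geodesic_km(*a, *b), rel=1e-9)

    def test_point_in_water_rejected(self, band_mask):
        with pytest.raises(ValueError, match="not on land"):
            circumnavigation_distance((12.0, -72.0), (20.0, -72.0), band_mask)

    def test_no_land_path_rejected(self):
        # water spanning the full longitude range of the polygon set plus
        # endpoints inside the gap is impossible; emulate with a ring
        ring = LandWaterMask({"ring": box(-80, 10, -60, 12)})
        # endpoints north and south of a band that spans all vertices:
        # going around the band's end is always possible on a finite band,
        # so instead verify the error with an endpoint enclosed by water
        enclosed = box(-75, 5, -70, 9)
        donut = box(-76, 4, -69, 10).difference(enclosed)
        mask = LandWaterMask({"donut": donut})
        with pytest.raises(ValueError, match="no land-constrained path"):
            circumnavigation_distance((7.0, -72.5), (20.0, -72.5), mask)
        del ring

    def test_symmetry(self, band_mask):
        a, b = (6.0, -72.0), (19.0, -75.0)
        d1 = circumnavigation_distance(a, b, band_mask)
        d2 = circumnavigation_distance(b, a, band_mask)
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_never_shorter_than_geodesic(self, band_mask):
        rng = np.random.default_rng(6)
        for _ in range(20):
            a = (float(rng.uniform(1, 7)), float(rng.uniform(-88, -62)))
            b = (float(rng.uniform(18, 25)), float(rng.uniform(-88, -62)))
            d = circumnavigation_distance(a, b, band_mask)
            assert d >= geodesic_km(*a, *b) - 1e-6

    def test_square_obstacle_matches_lattice_oracle(self):
        sq = box(-75.0, 10.0, -70.0, 15.0)
        mask = LandWaterMask({"sq": sq})
        a, b = (8.0, -72.5), (17.0, -72.5)
        mine = circumnavigation_distance(a, b, mask)
        oracle = lattice_path_km(a, b, [sq], geodesic_km)
        assert mine == pytest.approx(oracle, rel=0.01)
        assert mine >= geodesic_km(*a, *b)

    def test_random_polygon_fields_match_lattice_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            polys = []
            for _ in range(rng.integers(1, 3)):
                cx = rng.uniform(-78, -68)
                cy = rng.uniform(9, 14)
                w = rng.uniform(2, 5)
                h = rng.uniform(2, 4)
                polys.append(box(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2))
            mask = LandWaterMask({f"p{i}": p for i, p in enumerate(polys)})
            a, b = (5.0, -73.0), (18.0, -73.0)
            if not (mask.on_land(*a) and mask.on_land(*b)):
                continue
            mine = circumnavigation_distance(a, b, mask)
            oracle = lattice_path_km(a, b, polys, geodesic_km)
            assert mine == pytest.approx(oracle, rel=0.01)


class TestIdentifyDepartures:
    DEST = {"B1": "texas"}

    def test_crossing_run_yields_one_departure(self, band_mask):
        pts = [(4.0, -72.0), (6.0, -72.0), (7.9, -72.0), (11.0, -72.0),
               (14.0, -72.0), (17.5, -72.0), (20.0, -72.0)]
        segs = _segments(_track(pts), band_mask)
        deps = identify_departures(segs, band_mask, self.DEST)
        assert len(deps) == 1
        d = deps[0]
        assert d.decision == "cross" and d.waterbody == "sea"
        assert (d.fix.lat, d.fix.lon) == (7.9, -72.0)

    def test_coastal_turn_yields_detour(self, band_mask):
        # bird reaches the coast then turns ~west (90 deg off the optimal 0)
        pts = [(5.0, -72.0), (7.7, -72.0), (7.7, -74.5), (7.7, -77.0), (7.7, -79.5)]
        segs = _segments(_track(pts), band_mask)
        deps = identify_departures(segs, band_mask, self.DEST)
        assert len(deps) == 1
        d = deps[0]
        assert d.decision == "detour" and d.waterbody == "sea"
        assert (d.fix.lat, d.fix.lon) == (7.7, -72.0)

    def test_inland_track_yields_nothing(self, band_mask):
        pts = [(2.0, -86.0), (4.0, -86.0), (6.0, -86.0), (7.0, -86.5)]
        segs = _segments(_track(pts), band_mask)
        assert identify_departures(segs, band_mask, self.DEST) == []

    def test_missing_destination_rejected(self, band_mask):
        segs = _segments(_track([(2.0, -86.0), (4.0, -86.0)]), band_mask)
        with pytest.raises(ValueError, match="destination"):
            identify_departures(segs, band_mask, {})

    def test_night_flag_is_next_segment_phase(self, band_mask):
        pts = [(6.0, -72.0), (7.9, -72.0), (11.0, -72.0), (14.0, -72.0), (18.0, -72.0)]
        segs = _segments(_track(pts), band_mask)
        deps = identify_departures(segs, band_mask, self.DEST)
        first_water = next(s for s in segs if s.surface == "water")
        assert deps[0].night == (first_water.phase == "night")


class TestCrossingDistance:
    def test_barrier_extent_on_ray(self, band_mask):
        entry, exit_ = barrier_extent_km(band_mask, "sea", 7.0, -72.0, 0.0)
        assert entry == pytest.approx(111.0, abs=10.0)
        assert exit_ == pytest.approx(10.0 * 111.13, abs=15.0)

    def test_direct_cross_measures_to_landing_fix(self, band_mask):
        pts = [(6.0, -72.0), (7.9, -72.0), (12.0, -72.0), (17.3, -72.0), (19.0, -72.0)]
        fixes = _track(pts)
        segs = _segments(fixes, band_mask)
        (dep,) = identify_departures(segs, band_mask, {"B1": "texas"})
        dist, far = crossing_distance(dep, fixes, band_mask)
        assert (far.lat, far.lon) == (17.3, -72.0)
        assert dist == pytest.approx(geodesic_km(7.9, -72.0, 17.3, -72.0), rel=1e-9)

    def test_no_far_side_fix_excluded(self, band_mask):
        # track ends mid-water: no qualifying land fix beyond the barrier
        pts = [(6.0, -72.0), (7.9, -72.0), (12.0, -72.0)]
        fixes = _track(pts)
        segs = _segments(fixes, band_mask)
        (dep,) = identify_departures(segs, band_mask, {"B1": "texas"})
        with pytest.raises(DepartureExclusion, match="far side"):
            crossing_distance(dep, fixes, band_mask)

    def test_build_departure_table_excludes_with_reason(self, band_mask, flat_wind):
        pts = [(6.0, -72.0), (7.9, -72.0), (12.0, -72.0)]
        fixes = _track(pts)
        segs = _segments(fixes, band_mask)
        deps = identify_departures(segs, band_mask, {"B1": "texas"})
        kept, excluded = build_departure_table(deps, {"B1": fixes}, band_mask, flat_wind)
        assert kept == [] and len(excluded) == 1
        assert "far side" in excluded[0].excluded_reason
        # tailwind still measured before exclusion: v=-4 on a northward optimum
        assert excluded[0].tailwind_ms == pytest.approx(-4.0, abs=1e-9)

    def test_detour_hypothetical_crossing_measured(self, band_mask, flat_wind):
        # detour at the coast, then around the west end and north past the band
        pts = [(5.0, -72.0), (7.7, -72.0), (7.5, -75.5), (7.3, -79.0), (7.2, -83.2),
               (11.0, -83.4), (15.0, -83.4), (18.5, -83.4), (21.0, -80.0)]
        fixes = _track(pts)
        segs = _segments(fixes, band_mask)
        deps = identify_departures(segs, band_mask, {"B1": "texas"})
        detours = [d for d in deps if d.decision == "detour"]
        assert detours
        kept, _ = build_departure_table(detours, {"B1": fixes}, band_mask, flat_wind)
        assert kept
        d = kept[0]
        assert d.ratio == pytest.approx(d.cross_km / d.land_km)
        assert d.land_km >= geodesic_km(d.fix.lat, d.fix.lon, 18.5, -83.4) - 1e-6
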