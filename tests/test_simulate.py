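"""Synthetic world: determinism, geometry, wind statistics, truth records."""

import numpy as np
import pytest
import shapely

from nightcross import make_world, simulate_departures, simulate_tracks
from nightcross.crossing import barrier_extent_km
from nightcross.simulate import DOMAIN, write_fixture_set


@pytest.fixture(scope="module")
def world():
    return make_world(seed=3)


@pytest.fixture(scope="module")
def tracks(world):
    return simulate_tracks(world, seed=3)


class TestWorld:
    def test_same_seed_identical_worlds(self):
        w1, w2 = make_world(seed=5), make_world(seed=5)
        assert np.array_equal(w1.wind.u, w2.wind.u)
        assert np.array_equal(w1.wind.v, w2.wind.v)
        assert all(
            w1.mask.water_polygons[n].equals(w2.mask.water_polygons[n])
            for n in w1.mask.names
        )

    def test_two_named_water_bands(self, world):
        assert set(world.mask.names) == {"sea", "gulf"}

    def test_feasible_crossing_widths_in_study_range(self, world):
        # due-north width of each band, probed along its southern edge
        widths = []
        for name, geom in world.mask.water_polygons.items():
            x0, y0, x1, _ = geom.bounds
            for lon in np.linspace(x0 + 0.5, x1 - 0.5, 12):
                entry, exit_ = barrier_extent_km(
                    world.mask, name, y0 - 0.5, lon, 0.0
                )
                widths.append(exit_ - entry)
        assert 90.0 <= min(widths) and max(widths) <= 1200.0

    def test_wind_mean_near_configured_vector(self):
        w = make_world(seed=9, mean_wind=(-2.0, -1.0), wind_sd=2.0)
        n_t = w.wind.u.shape[0]
        # AR(1) time-mean SE: sd/sqrt(n_eff), n_eff = n(1-rho)/(1+rho)
        se = 2.0 / np.sqrt(n_t * (1 - 0.75) / (1 + 0.75))
        assert abs(w.wind.u.mean() + 2.0) < 4 * se
        assert abs(w.wind.v.mean() + 1.0) < 4 * se

    def test_grid_spacing_matches_reanalysis_layout(self, world):
        assert np.allclose(np.diff(world.wind.lats), 2.5)
        assert np.allclose(np.diff(world.wind.lons), 2.5)
        dt = np.diff(world.wind.times.asi8)
        assert np.all(dt == 6 * 3600 * 10**9)


class TestTracks:
    def test_same_seed_identical_tracks(self, world):
        f1, t1 = simulate_tracks(world, seed=11)
        f2, t2 = simulate_tracks(world, seed=11)
        assert f1 == f2
        assert t1["departures"].equals(t2["departures"])

    def test_fixes_inside_wind_envelope(self, world, tracks):
        fixes, _ = tracks
        for f in fixes:
            assert world.wind.lats[0] <= f.lat <= world.wind.lats[-1]
            assert world.wind.lons[0] <= f.lon <= world.wind.lons[-1]
            assert world.wind.times[0] <= f.t.replace(tzinfo=None) <= world.wind.times[-1]

    def test_schedule_mix_matches_study(self, tracks):
        _, truth = tracks
        slots = [tuple(s.daily_slots) for s in truth["schedules"].values()]
        assert slots.count(("0600", "1800")) == 7
        assert slots.count(("0400", "1600")) == 2
        assert slots.count(("0400", "1000", "1600")) == 1
        assert slots.count(("0000", "0600", "1800")) == 1

    def test_truth_departures_complete(self, tracks):
        _, truth = tracks
        td = truth["departures"]
        assert set(td.decision) <= {"cross", "detour"}
        assert (td.ratio > 0).all()
        assert np.isfinite(td.tailwind_ms).all()
        assert len(td) >= 11  # every bird faces at least the first band

    def test_airspeed_bounded_between_fixes(self, world, tracks):
        from nightcross.geo import geodesic_km

        fixes, _ = tracks
        by_bird = {}
        for f in fixes:
            by_bird.setdefault(f.bird_id, []).append(f)
        for bf in by_bird.values():
            for a, b in zip(bf, bf[1:]):
                hours = (b.t - a.t).total_seconds() / 3600.0
                if hours <= 0:
                    continue
                speed = geodesic_km(a.lat, a.lon, b.lat, b.lon) / hours
                assert speed <= 85.0  # generator's hard ceiling is 80 km/h

    def test_long_crossings_span_night(self, world, tracks):
        # a crossing that takes more than one 12-h interval necessarily
        # includes a night interval (phases alternate), mirroring birds
        # that cannot finish a large crossing within daylight hours
        fixes, truth = tracks
        by_bird = {}
        for f in fixes:
            by_bird.setdefault(f.bird_id, []).append(f)
        checked = 0
        for _, dep in truth["departures"].iterrows():
            if dep["decision"] != "cross":
                continue
            after = [f for f in by_bird[dep["bird_id"]] if f.t > dep["time"]]
            over_water = [
                f for f in after if not world.mask.on_land(f.lat, f.lon)
            ]
            if not over_water:
                continue
            landing = min(
                (f for f in after if f.t > over_water[-1].t and world.mask.on_land(f.lat, f.lon)),
                key=lambda f: f.t,
                default=None,
            )
            if landing is None:
                continue
            flight_min = (landing.t - dep["time"]).total_seconds() / 60.0
            if flight_min > 720.0:
                # phases alternate every 12 h: the span covers both
                n_intervals = int(np.ceil(flight_min / 720.0))
                assert n_intervals >= 2
                checked += 1
        assert checked >= 3  # the ~1000-km band cannot be crossed in 12 h


class TestSimulateDepartures:
    def test_determinism(self):
        d1, t1 = simulate_departures(seed=4)
        d2, t2 = simulate_departures(seed=4)
        assert d1.equals(d2)
        assert t1["u_birds"] == t2["u_birds"]

    def test_null_model_fair_coin(self):
        df, _ = simulate_departures(4000, 40, (0.0, 0.0, 0.0, 0.0), 0.0, seed=13)
        # binomial 4 sigma around 0.5
        assert abs(df.cross.mean() - 0.5) < 4 * 0.5 / np.sqrt(4000)

    def test_strong_ratio_penalty_mostly_detours(self):
        df, _ = simulate_departures(400, 20, (0.0, 0.0, -6.0, 0.0), 0.0, seed=14)
        high = df[df.ratio > df.ratio.quantile(0.8)]
        assert high.cross.mean() < 0.1

    def test_covariates_standardized_as_inference_will(self):
        from nightcross.crossing import scale_center

        df, truth = simulate_departures(200, 20, (2, 1, -2, -1), 0.5, seed=15)
        tw_s = scale_center(df["tailwind_ms"])
        assert tw_s.mean() == pytest.approx(0.0, abs=1e-12)
        assert tw_s.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert len(truth["p_cross"]) == 200


class TestCovariateRecovery:
    def test_pipeline_covariates_match_truth_at_cross_departures(self, world, tracks):
        from nightcross import analyze_tracks

        fixes, truth = tracks
        res = analyze_tracks(
            fixes, truth["schedules"], world.mask, world.wind,
            chains=2, iterations=200, seed=3, compute_daylight=False,
        )
        found = res["departure_frame"]
        td = truth["departures"]
        import pandas as pd

        found_t = pd.to_datetime(found["time"], format="ISO8601")
        n_checked = 0
        for _, tr in td.iterrows():
            m = found[
                (found["bird_id"] == tr["bird_id"])
                & (found["waterbody"] == tr["waterbody"])
                & (found_t == tr["time"])
            ]
            if m.empty:
                continue
            row = m.iloc[0]
            assert abs(row["tailwind_ms"] - tr["tailwind_ms"]) < 0.1
            if tr["decision"] == "cross" and row["decision"] == "cross" and row["ratio"] is not None:
                assert abs(row["ratio"] - tr["ratio"]) < 0.05
                n_checked += 1
        assert n_checked >= 5

    def test_recovery_experiment_reports_per_seed(self, world):
        from nightcross import recovery_experiment

        report = recovery_experiment(
            world, n_birds=11, true_beta=(2, 1, -2, -1), sigma_bird=0.5,
            seeds=[21, 22], chains=2, iterations=400,
        )
        assert len(report) == 2
        ok = report[report["failed_stage"].isna()]
        assert len(ok) == 2, report["failed_stage"].tolist()
        assert (ok["recall"] >= 0.9).all()
        for col in ("est_Intercept", "bias_Water:Land", "cover_Tailwind"):
            assert col in report.columns

    def test_fixture_set_roundtrips_through_loaders(self, world, tracks, tmp_path):
        from nightcross import LandWaterMask, WindGrid, load_schedules, read_fixes

        fixes, truth = tracks
        paths = write_fixture_set(world, fixes, truth, tmp_path, wind_format="nc")
        schedules = load_schedules(paths["schedules"])
        assert set(schedules) == set(truth["schedules"])
        re_fixes = read_fixes(paths["fixes"], schedules)
        assert len(re_fixes) == len(fixes)
        assert re_fixes[0].slot == fixes[0].slot
        mask = LandWaterMask.from_geojson(paths["mask"])
        assert set(mask.names) == {"sea", "gulf"}
        wind = WindGrid.from_netcdf(paths["wind"])
        assert np.allclose(wind.u, world.wind.u, atol=1e-5)
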