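"""End-to-end orchestration: files in, tabular artifacts out.

Every stage's row counts are logged as line-delimited JSON so exclusions
are auditable: fixes in = fixes kept + fixes trimmed, departures in the
model = departures found - exclusions (each exclusion carries a reason).
All randomness funnels through the single config seed; artifacts are
plain CSV so a rerun with the same config is byte-identical and any
stage can be diffed or re-entered.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crossing import build_departure_table, departures_to_frame, identify_departures
from .geo import initial_bearing
from .model import CrossingModel, DaylightTrendModel
from .movement import LandWaterMask, bird_summary, classify_surface, summaries_to_frames
from .solar import daylight_overlap
from .tracks import (
    GPSFix,
    TagSchedule,
    build_segments,
    load_schedules,
    normalize_schedule,
    read_fixes,
    trim_migration,
)
from .wind import WindGrid, bearing_histogram, speed_dir, windrose_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, thresholds and model settings for one pipeline run."""

    fixes: str = ""
    schedules: str = ""
    mask: str = ""
    wind: str = ""
    out_dir: str = "results"
    surface_majority: float = 0.5
    surface_step_km: float = 1.0
    coastal_buffer_km: float = 50.0
    min_block_km: float = 100.0
    detour_angle_deg: float = 60.0
    stationary_radius_km: float = 30.0
    stationary_days: float = 3.0
    chains: int = 4
    iterations: int = 2000
    seed: int = 42
    compute_daylight: bool = True

    def __post_init__(self):
        for name in (
            "surface_majority", "surface_step_km", "coastal_buffer_km",
            "min_block_km", "detour_angle_deg", "stationary_radius_km",
            "stationary_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _log_stage(stage: str, **counts):
    logger.info(json.dumps({"stage": stage, **counts}, default=str))


def analyze_tracks(
    fixes: list[GPSFix],
    schedules: dict[str, TagSchedule],
    mask: LandWaterMask,
    wind: WindGrid,
    *,
    surface_majority: float = 0.5,
    surface_step_km: float = 1.0,
    coastal_buffer_km: float = 50.0,
    min_block_km: float = 100.0,
    detour_angle_deg: float = 60.0,
    stationary_radius_km: float = 30.0,
    stationary_days: float = 3.0,
    chains: int = 4,
    iterations: int = 2000,
    seed: int | None = None,
    compute_daylight: bool = True,
) -> dict:
    """Run the in-memory analysis: segments, summaries, departures, models."""
    by_bird: dict[str, list[GPSFix]] = {}
    for f in fixes:
        by_bird.setdefault(f.bird_id, []).append(f)
    _log_stage("ingest", n_fixes=len(fixes), n_birds=len(by_bird))

    segments = []
    trimmed_by_bird: dict[str, list[GPSFix]] = {}
    n_trimmed = 0
    for bird_id, bf in by_bird.items():
        kept = trim_migration(bf, stationary_radius_km, stationary_days)
        n_trimmed += len(bf) - len(kept)
        kept = normalize_schedule(kept, schedules[bird_id])
        trimmed_by_bird[bird_id] = kept
        segments.extend(build_segments(kept, schedules[bird_id]))
    _log_stage(
        "segment", n_fixes_kept=sum(map(len, trimmed_by_bird.values())),
        n_fixes_trimmed=n_trimmed, n_segments=len(segments),
    )

    for seg in segments:
        classify_surface(seg, mask, step_km=surface_step_km, majority=surface_majority)
        if compute_daylight:
            seg.daylight_min = daylight_overlap(seg)

    summaries = []
    for bird_id in sorted(trimmed_by_bird):
        segs = [s for s in segments if s.bird_id == bird_id]
        if segs:
            summaries.append(bird_summary(segs))

    destinations = {b: s.destination for b, s in schedules.items()}
    departures = identify_departures(
        segments, mask, destinations,
        coastal_buffer_km=coastal_buffer_km,
        min_block_km=min_block_km,
        detour_angle_deg=detour_angle_deg,
    )
    kept, excluded = build_departure_table(departures, trimmed_by_bird, mask, wind)
    _log_stage(
        "departures", n_found=len(departures), n_excluded=len(excluded),
        n_model=len(kept),
    )

    fit = None
    if kept:
        outcomes = {d.decision for d in kept}
        if len(outcomes) > 1 and len({d.bird_id for d in kept}) >= 2:
            fit = CrossingModel.from_departures(kept).fit(
                chains=chains, iterations=iterations, seed=seed
            )
        else:
            _log_stage("model", skipped="outcomes or birds insufficient")

    daylight_fits = {}
    if compute_daylight:
        for phase in ("day", "night"):
            try:
                daylight_fits[phase] = DaylightTrendModel.from_segments(segments, phase).fit()
            except ValueError as exc:
                _log_stage("daylight_regression", phase=phase, skipped=str(exc))

    wind_samples, bearings = [], []
    for d in departures:
        u, v = wind.interp_uv(d.fix.lat, d.fix.lon, d.fix.t)
        wind_samples.append((d.decision, speed_dir(u, v)))
        nxt = [s for s in segments if s.bird_id == d.bird_id and s.start_fix.t == d.fix.t]
        if nxt and nxt[0].distance_km > 0:
            s = nxt[0]
            bearings.append(
                (d.decision,
                 initial_bearing(s.start_fix.lat, s.start_fix.lon, s.end_fix.lat, s.end_fix.lon))
            )

    from .tracks import segments_to_frame

    return {
        "segments": segments,
        "segment_frame": segments_to_frame(segments),
        "summaries": summaries,
        "departures": departures,
        "kept_departures": kept,
        "excluded_departures": excluded,
        "departure_frame": departures_to_frame(departures),
        "fit": fit,
        "daylight_fits": daylight_fits,
        "wind_samples": wind_samples,
        "bearings": bearings,
    }


ARTIFACTS = (
    "segments.csv", "summary_counts.csv", "summary_distances.csv",
    "summary_speeds.csv", "departures.csv", "model_summary.csv",
    "bayes_r2.csv", "daylight_regression.csv", "windrose.csv", "bearings.csv",
)


def validate_inputs(config: PipelineConfig) -> dict:
    """Schema-check every input file; report per-file pass/fail."""
    report: dict[str, dict] = {}

    def _check(name, fn):
        try:
            fn()
            report[name] = {"ok": True}
        except Exception as exc:  # noqa: BLE001 - report-only contract
            report[name] = {"ok": False, "error": str(exc)}

    def _fixes():
        df = pd.read_csv(config.fixes)
        missing = {"bird_id", "timestamp", "lat", "lon"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {sorted(missing)}")
        bad_lat = df.index[(df["lat"] < -90) | (df["lat"] > 90)]
        if len(bad_lat):
            raise ValueError(f"row {bad_lat[0] + 2}: lat {df.loc[bad_lat[0], 'lat']} out of bounds")
        bad_lon = df.index[(df["lon"] < -180) | (df["lon"] > 180)]
        if len(bad_lon):
            raise ValueError(f"row {bad_lon[0] + 2}: lon {df.loc[bad_lon[0], 'lon']} out of bounds")
        pd.to_datetime(df["timestamp"], format="ISO8601")

    def _wind():
        if str(config.wind).endswith(".csv"):
            WindGrid.from_csv(config.wind)
        else:
            WindGrid.from_netcdf(config.wind)

    _check("fixes", _fixes)
    _check("schedules", lambda: load_schedules(config.schedules))
    _check("mask", lambda: LandWaterMask.from_geojson(config.mask))
    _check("wind", _wind)
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline from files and write all artifacts.

    Returns the analysis dict; raises :class:`PipelineError` (after
    writing a manifest naming the failing stage) on any stage failure.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_digest": config.digest,
        "seed": config.seed,
        "versions": {
            "nightcross": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
    }
    stage = "load"
    try:
        schedules = load_schedules(config.schedules)
        mask = LandWaterMask.from_geojson(config.mask)
        wind = (
            WindGrid.from_csv(config.wind)
            if str(config.wind).endswith(".csv")
            else WindGrid.from_netcdf(config.wind)
        )
        fixes = read_fixes(config.fixes, schedules)
        manifest["stages"]["load"] = {"n_fixes": len(fixes)}

        stage = "analyze"
        res = analyze_tracks(
            fixes, schedules, mask, wind,
            surface_majority=config.surface_majority,
            surface_step_km=config.surface_step_km,
            coastal_buffer_km=config.coastal_buffer_km,
            min_block_km=config.min_block_km,
            detour_angle_deg=config.detour_angle_deg,
            stationary_radius_km=config.stationary_radius_km,
            stationary_days=config.stationary_days,
            chains=config.chains,
            iterations=config.iterations,
            seed=config.seed,
            compute_daylight=config.compute_daylight,
        )
        manifest["stages"]["analyze"] = {
            "n_segments": len(res["segments"]),
            "n_departures_found": len(res["departures"]),
            "n_departures_excluded": len(res["excluded_departures"]),
            "n_departures_model": len(res["kept_departures"]),
            "exclusion_reasons": [d.excluded_reason for d in res["excluded_departures"]],
        }

        stage = "write"
        res["segment_frame"].to_csv(out / "segments.csv", index=False)
        t1, t2, t3 = summaries_to_frames(res["summaries"])
        t1.to_csv(out / "summary_counts.csv", index=False)
        t2.to_csv(out / "summary_distances.csv", index=False)
        t3.to_csv(out / "summary_speeds.csv", index=False)
        res["departure_frame"].to_csv(out / "departures.csv", index=False)

        if res["fit"] is not None:
            res["fit"].summary().to_csv(out / "model_summary.csv")
            r2, (r2_lo, r2_hi) = res["fit"].bayes_r2()
            pd.DataFrame(
                [{"bayes_r2": r2, "l95": r2_lo, "u95": r2_hi}]
            ).to_csv(out / "bayes_r2.csv", index=False)
            res["fit"].to_frame().to_csv(out / "posterior_draws.csv", index=False)
        else:
            pd.DataFrame(columns=["Covariate"]).to_csv(out / "model_summary.csv", index=False)
            pd.DataFrame(columns=["bayes_r2", "l95", "u95"]).to_csv(out / "bayes_r2.csv", index=False)

        dl = [f.summary() for f in res["daylight_fits"].values()]
        (pd.concat(dl, ignore_index=True) if dl else pd.DataFrame()).to_csv(
            out / "daylight_regression.csv", index=False
        )
        windrose_table([s for _, s in res["wind_samples"]]).to_csv(out / "windrose.csv")
        hist = bearing_histogram([b for _, b in res["bearings"]])
        pd.DataFrame(
            {"sector_center_deg": [i * 22.5 for i in range(16)], "count": hist}
        ).to_csv(out / "bearings.csv", index=False)

        manifest["artifacts"] = sorted(p.name for p in out.glob("*.csv"))
        manifest["status"] = "ok"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return res
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, exc) from exc
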