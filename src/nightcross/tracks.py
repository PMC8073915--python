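"""GPS fix ingestion and 12-h day/night track segmentation.

Tags log positions two or three times a day at fixed local clock times
(e.g. 0600 and 1800 CDT).  Consecutive scheduled fixes bound nominal
12-hour *segments*, each classified as a day flight or a night flight
from the slot that opens it.  Three-slot tags carry one extra fix in the
middle of one 12-h interval; that fix is kept as a *waypoint* refining
the segment's path distance but never defines a phase boundary, which
makes three-slot tracks comparable with two-slot ones.

All internal times are UTC.  Tag schedules are declared with fixed
daylight-time offsets (CDT = UTC-5, EDT = UTC-4); daylight-saving
transitions are ignored because the tags themselves used fixed labels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta, timezone
from pathlib import Path

import pandas as pd
import yaml

from .geo import geodesic_km

logger = logging.getLogger(__name__)

ALLOWED_SLOTS = {"0000", "0400", "0600", "1000", "1600", "1800"}
SLOT_TOLERANCE_MIN = 30.0
#: nominal 12-h interval tolerance; wide enough for fix-acquisition jitter,
#: narrow enough never to merge two distinct scheduled intervals
SEGMENT_TOLERANCE_H = 1.0


def _slot_minutes(slot: str) -> int:
    return int(slot[:2]) * 60 + int(slot[2:])


@dataclass(frozen=True)
class GPSFix:
    """One timestamped tag position."""

    bird_id: str
    t: datetime  # aware, UTC
    lat: float
    lon: float
    slot: str = "adhoc"
    waypoint: bool = False

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} out of bounds")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} out of bounds")
        if self.t.tzinfo is None:
            raise ValueError("fix timestamps must be timezone-aware UTC")


@dataclass(frozen=True)
class TagSchedule:
    """A tag's daily fix schedule in its fixed local daylight time."""

    bird_id: str
    local_utc_offset: float  # hours; CDT = -5, EDT = -4
    daily_slots: tuple[str, ...]
    night_window: tuple[str, str] = ()  # inferred when empty
    destination: str | None = None

    def __post_init__(self):
        bad = set(self.daily_slots) - ALLOWED_SLOTS
        if bad:
            raise ValueError(f"unknown slots {sorted(bad)} for bird {self.bird_id}")
        if not self.night_window:
            object.__setattr__(self, "night_window", self._infer_night_window())
        s, e = self.night_window
        if (_slot_minutes(e) - _slot_minutes(s)) % (24 * 60) != 12 * 60:
            raise ValueError(f"night window {self.night_window} does not span 12 h")

    def _infer_night_window(self) -> tuple[str, str]:
        # the interval anchors are the slot pair exactly 12 h apart; the
        # evening member (1600 or 1800) opens the night interval
        slots = sorted(self.daily_slots, key=_slot_minutes)
        for s in slots:
            partner = (_slot_minutes(s) + 12 * 60) % (24 * 60)
            for e in slots:
                if _slot_minutes(e) == partner and s in ("1600", "1800"):
                    return (s, e)
        raise ValueError(
            f"slots {self.daily_slots} do not bracket a 12-h night window"
        )

    @property
    def anchors(self) -> tuple[str, str]:
        """The two slots bounding the 12-h day and night intervals."""
        return self.night_window

    def local_minutes(self, t: datetime) -> float:
        """Minutes past local midnight of an aware timestamp."""
        local = t.astimezone(timezone.utc) + timedelta(hours=self.local_utc_offset)
        return local.hour * 60 + local.minute + local.second / 60.0


@dataclass
class TrackSegment:
    """A nominal 12-h flight interval between consecutive scheduled fixes."""

    bird_id: str
    start_fix: GPSFix
    end_fix: GPSFix
    phase: str  # "day" | "night"
    duration_h: float
    distance_km: float
    waypoints: tuple[GPSFix, ...] = ()
    surface: str | None = None  # "land" | "water", set by classify_surface
    water_km: float | None = None
    daylight_min: float | None = None

    @property
    def speed_kmh(self) -> float:
        if self.duration_h <= 0:
            raise ValueError("segment duration must be positive")
        return self.distance_km / self.duration_h


def load_schedules(path) -> dict[str, TagSchedule]:
    """Read tag schedules from a YAML or JSON config keyed by bird_id.

    Each entry needs ``offset_hours`` and ``slots``; ``night_window`` and
    ``destination`` are optional.
    """
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    out = {}
    for bird_id, cfg in raw.items():
        out[bird_id] = TagSchedule(
            bird_id=str(bird_id),
            local_utc_offset=float(cfg["offset_hours"]),
            daily_slots=tuple(str(s).zfill(4) for s in cfg["slots"]),
            night_window=tuple(cfg.get("night_window", ())),
            destination=cfg.get("destination"),
        )
    return out


def assign_slot(t: datetime, schedule: TagSchedule) -> str:
    """Nearest scheduled slot (±30 min, circular over the day) or "adhoc"."""
    m = schedule.local_minutes(t)
    best, best_d = None, None
    for s in schedule.daily_slots:
        d = abs((m - _slot_minutes(s) + 720) % 1440 - 720)
        if best_d is None or d < best_d:
            best, best_d = s, d
    if best_d is not None and best_d <= SLOT_TOLERANCE_MIN:
        return best
    return "adhoc"


def read_fixes(path, schedules: dict[str, TagSchedule]) -> list[GPSFix]:
    """Parse a fix CSV (bird_id, timestamp, lat, lon) into sorted GPSFixes.

    Rows are validated one by one so a malformed row raises an error that
    names its line number (header = line 1).  Fixes whose time matches no
    scheduled slot within 30 min are kept with slot "adhoc" and a warning.
    """
    df = pd.read_csv(path, dtype={"bird_id": str})
    required = {"bird_id", "timestamp", "lat", "lon"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fix file {path} missing columns {sorted(missing)}")
    fixes: list[GPSFix] = []
    for idx, row in df.iterrows():
        line = idx + 2
        bird = row["bird_id"]
        if bird not in schedules:
            raise ValueError(f"line {line}: unknown bird_id {bird!r}")
        try:
            t = datetime.fromisoformat(str(row["timestamp"]).replace("Z", "+00:00"))
            if t.tzinfo is None:
                t = t.replace(tzinfo=timezone.utc)
            fix = GPSFix(bird, t.astimezone(timezone.utc), float(row["lat"]), float(row["lon"]))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"line {line}: malformed fix row ({exc})") from None
        slot = assign_slot(fix.t, schedules[bird])
        if slot == "adhoc":
            warnings.warn(
                f"line {line}: fix time matches no slot of bird {bird} within "
                f"{SLOT_TOLERANCE_MIN:.0f} min; kept as adhoc"
            )
        fixes.append(replace(fix, slot=slot))
    fixes.sort(key=lambda f: (f.bird_id, f.t))
    for a, b in zip(fixes, fixes[1:]):
        if a.bird_id == b.bird_id and a.t == b.t:
            raise ValueError(f"duplicate timestamp {a.t} for bird {a.bird_id}")
    return fixes


def normalize_schedule(fixes: list[GPSFix], schedule: TagSchedule) -> list[GPSFix]:
    """Collapse a 3-slot schedule onto its 12-h day/night anchor intervals.

    The two slots 12 h apart remain segment endpoints; the third slot's
    fixes are marked as waypoints (path refinement only).  Two-slot
    schedules pass through unchanged; the operation is idempotent.
    """
    anchors = set(schedule.anchors)
    out = []
    for f in fixes:
        if f.bird_id != schedule.bird_id:
            raise ValueError("normalize_schedule expects fixes of a single bird")
        wp = f.slot not in anchors
        out.append(replace(f, waypoint=wp) if wp != f.waypoint else f)
    return out


def build_segments(fixes: list[GPSFix], schedule: TagSchedule) -> list[TrackSegment]:
    """Chain consecutive anchor fixes ~12 h apart into day/night segments.

    Gaps longer than 12 h ± 1 h break the chain (logged, never an error).
    A segment's distance is the great-circle path through any waypoints
    recorded inside it; its phase is night iff its opening slot is the
    night-window start.
    """
    fixes = sorted(fixes, key=lambda f: f.t)
    anchors = [f for f in fixes if not f.waypoint and f.slot in schedule.anchors]
    waypoints = [f for f in fixes if f.waypoint]
    night_start = schedule.night_window[0]
    segments: list[TrackSegment] = []
    for a, b in zip(anchors, anchors[1:]):
        dt_h = (b.t - a.t).total_seconds() / 3600.0
        if abs(dt_h - 12.0) > SEGMENT_TOLERANCE_H:
            logger.info(
                "gap for bird %s: %.1f h between %s and %s", a.bird_id, dt_h, a.t, b.t
            )
            continue
        inner = tuple(w for w in waypoints if a.t < w.t < b.t)
        pts = [a, *inner, b]
        dist = float(
            sum(
                geodesic_km(p.lat, p.lon, q.lat, q.lon)
                for p, q in zip(pts, pts[1:])
            )
        )
        segments.append(
            TrackSegment(
                bird_id=a.bird_id,
                start_fix=a,
                end_fix=b,
                phase="night" if a.slot == night_start else "day",
                duration_h=dt_h,
                distance_km=dist,
                waypoints=inner,
            )
        )
    return segments


def trim_migration(
    fixes: list[GPSFix],
    stationary_radius_km: float = 30.0,
    stationary_days: float = 3.0,
) -> list[GPSFix]:
    """Drop leading/trailing stationary runs (wintering and breeding sites).

    A run is stationary when every fix lies within ``stationary_radius_km``
    of the run's first fix; leading and trailing maximal stationary runs
    spanning at least ``stationary_days`` are removed.  Interior fixes are
    never touched.  A fully stationary track returns empty with a warning.
    """
    if not fixes:
        return []
    fixes = sorted(fixes, key=lambda f: f.t)

    def _run_len(seq: list[GPSFix]) -> int:
        n = 1
        while n < len(seq) and geodesic_km(seq[0].lat, seq[0].lon, seq[n].lat, seq[n].lon) <= stationary_radius_km:
            n += 1
        return n

    lead = _run_len(fixes)
    if (
        lead == len(fixes)
        and (fixes[-1].t - fixes[0].t) >= timedelta(days=stationary_days)
    ):
        warnings.warn(f"bird {fixes[0].bird_id}: all fixes stationary; track trimmed away")
        return []
    if (fixes[lead - 1].t - fixes[0].t) >= timedelta(days=stationary_days):
        fixes = fixes[lead:]
    rev = fixes[::-1]
    trail = _run_len(rev)
    if trail < len(rev) and (rev[0].t - rev[trail - 1].t) >= timedelta(days=stationary_days):
        fixes = fixes[: len(fixes) - trail]
    return fixes


def segments_to_frame(segments: list[TrackSegment]) -> pd.DataFrame:
    """Flatten segments into the tabular CSV layout used by the pipeline."""
    rows = []
    for s in segments:
        rows.append(
            {
                "bird_id": s.bird_id,
                "t_start": s.start_fix.t.isoformat(),
                "t_end": s.end_fix.t.isoformat(),
                "lat_start": s.start_fix.lat,
                "lon_start": s.start_fix.lon,
                "lat_end": s.end_fix.lat,
                "lon_end": s.end_fix.lon,
                "phase": s.phase,
                "duration_h": s.duration_h,
                "distance_km": s.distance_km,
                "surface": s.surface,
                "water_km": s.water_km,
                "daylight_min": s.daylight_min,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "bird_id", "t_start", "t_end", "lat_start", "lon_start",
            "lat_end", "lon_end", "phase", "duration_h", "distance_km",
            "surface", "water_km", "daylight_min",
        ],
    )
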