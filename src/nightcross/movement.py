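"""Land/water flight classification and per-bird movement summaries.

A segment is a *water flight* when the majority of its great-circle path
lies over a named water polygon (Caribbean Sea, Gulf of Mexico, ...).
Summaries per bird report flight counts, distance means, speeds and
24-h maxima split by the phase x surface cells (day/land, night/land,
day/water, night/water).

Standard-error convention: cell SEs use the population standard
deviation (divisor n) over sqrt(n).  This differs from the common n-1
sample convention; it is the convention under which a single-flight
cell prints "± 0.00" and group means over per-bird totals match the
reported scale of this kind of tracking summary, and it is applied
uniformly by :func:`group_mean_se`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.ops import nearest_points, unary_union

from .geo import gc_points, geodesic_km
from .tracks import TrackSegment

PHASES = ("day", "night")
SURFACES = ("land", "water")


class LandWaterMask:
    """Named water polygons in lon/lat degrees; everything else is land."""

    def __init__(self, water_polygons: dict):
        for name, geom in water_polygons.items():
            if not geom.is_valid:
                raise ValueError(f"water polygon {name!r} is not a valid geometry")
        self.water_polygons = dict(water_polygons)
        self._union = unary_union(list(water_polygons.values())) if water_polygons else None

    @classmethod
    def from_geojson(cls, path) -> "LandWaterMask":
        gj = json.loads(Path(path).read_text())
        polys = {}
        for feat in gj.get("features", []):
            name = feat.get("properties", {}).get("name")
            if name is None:
                raise ValueError("mask feature without a 'name' property")
            if name in polys:
                raise ValueError(f"duplicate water polygon name {name!r}")
            polys[name] = shapely_shape(feat["geometry"])
        return cls(polys)

    def to_geojson(self, path) -> None:
        feats = [
            {
                "type": "Feature",
                "properties": {"name": name},
                "geometry": json.loads(shapely.to_geojson(geom)),
            }
            for name, geom in self.water_polygons.items()
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": feats})
        )

    @property
    def names(self):
        return list(self.water_polygons)

    def on_land(self, lat: float, lon: float) -> bool:
        if self._union is None:
            return True
        return not self._union.covers(shapely.Point(lon, lat))

    def water_points(self, lats, lons) -> np.ndarray:
        """Boolean array: which (lat, lon) points fall in any water polygon."""
        pts = shapely.points(np.asarray(lons, float), np.asarray(lats, float))
        if self._union is None:
            return np.zeros(len(pts), bool)
        return shapely.covers(self._union, pts)

    def water_km_along(self, lat1, lon1, lat2, lon2, step_km: float = 1.0) -> dict:
        """km of the great-circle path inside each water polygon.

        The path is sampled every ``step_km``; each step is attributed to
        the polygon containing its midpoint.
        """
        total = float(geodesic_km(lat1, lon1, lat2, lon2))
        out = {name: 0.0 for name in self.water_polygons}
        if total <= 0 or not self.water_polygons:
            return out
        n_steps = max(1, int(math.ceil(total / step_km)))
        lats, lons = gc_points(lat1, lon1, lat2, lon2, n_steps + 1)
        mid_lat = 0.5 * (lats[:-1] + lats[1:])
        mid_lon = 0.5 * (lons[:-1] + lons[1:])
        step_len = total / n_steps
        mids = shapely.points(mid_lon, mid_lat)
        for name, geom in self.water_polygons.items():
            inside = shapely.covers(geom, mids)
            out[name] = float(inside.sum() * step_len)
        return out

    def distance_to_water_km(self, lat: float, lon: float) -> dict:
        """Geodesic km from a point to the nearest boundary of each polygon."""
        p = shapely.Point(lon, lat)
        out = {}
        for name, geom in self.water_polygons.items():
            q = nearest_points(geom, p)[0]
            out[name] = float(geodesic_km(lat, lon, q.y, q.x))
        return out


def classify_surface(
    segment: TrackSegment,
    mask: LandWaterMask,
    step_km: float = 1.0,
    majority: float = 0.5,
) -> tuple[str, float]:
    """Label a segment land or water and measure its over-water km.

    The endpoint-to-endpoint great circle is sampled every ``step_km``;
    the segment is water iff the over-water fraction exceeds
    ``majority``.  Zero-distance segments are land.  The segment's
    ``surface`` and ``water_km`` fields are filled in place and the pair
    is returned.
    """
    per_poly = mask.water_km_along(
        segment.start_fix.lat, segment.start_fix.lon,
        segment.end_fix.lat, segment.end_fix.lon, step_km,
    )
    water_km = float(sum(per_poly.values()))
    endpoint_km = float(
        geodesic_km(segment.start_fix.lat, segment.start_fix.lon,
                    segment.end_fix.lat, segment.end_fix.lon)
    )
    surface = "water" if endpoint_km > 0 and water_km / endpoint_km > majority else "land"
    segment.surface = surface
    segment.water_km = water_km
    return surface, water_km


def segment_speed(segment: TrackSegment) -> float:
    """Ground speed in km/h over the segment's elapsed time."""
    return segment.speed_kmh


def max_24h_distance(segments: list[TrackSegment], window_h: float = 24.0) -> float:
    """Longest summed flight distance within any 24-h span of segments.

    Windows are runs of consecutive segments whose elapsed time (first
    start to last end) stays within ``window_h`` plus the 1-h fix jitter
    tolerance.  Empty input gives 0.
    """
    if not segments:
        return 0.0
    segs = sorted(segments, key=lambda s: s.start_fix.t)
    best = 0.0
    for i in range(len(segs)):
        total = 0.0
        for j in range(i, len(segs)):
            elapsed = (segs[j].end_fix.t - segs[i].start_fix.t).total_seconds() / 3600.0
            if elapsed > window_h + 1.0:
                break
            total += segs[j].distance_km
            best = max(best, total)
    return best


def group_mean_se(values) -> tuple[float, float]:
    """Mean and standard error with the population-SD (divisor n) convention."""
    x = np.asarray(list(values), float)
    if x.size == 0:
        raise ValueError("group_mean_se needs at least one value")
    mean = float(x.mean())
    se = float(x.std(ddof=0) / math.sqrt(x.size))
    return mean, se


def percent_of(count: int, total: int) -> int:
    """Integer percent, rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    return int(math.floor(100.0 * count / total + 0.5))


@dataclass
class BirdSummary:
    """Per-bird flight counts, distances and speeds by phase x surface."""

    bird_id: str
    n_day_water: int
    n_night_water: int
    total_km: float
    max_24h_km: float
    #: (phase, surface) -> (n, mean_km, se_km); absent cells omitted
    distance_cells: dict = field(default_factory=dict)
    #: (phase, surface) -> (mean_kmh, se_kmh, max_kmh)
    speed_cells: dict = field(default_factory=dict)


def bird_summary(segments: list[TrackSegment]) -> BirdSummary:
    """Summarise one bird's classified segments.

    Cells with no segments are simply absent from the cell dicts (they
    print as "-" in tabular output).
    """
    if not segments:
        raise ValueError("bird_summary needs at least one segment")
    bird_id = segments[0].bird_id
    cells: dict[tuple[str, str], list[TrackSegment]] = {}
    for s in segments:
        if s.surface not in SURFACES:
            raise ValueError("segments must be surface-classified first")
        cells.setdefault((s.phase, s.surface), []).append(s)
    distance_cells, speed_cells = {}, {}
    for key, segs in cells.items():
        d_mean, d_se = group_mean_se([s.distance_km for s in segs])
        distance_cells[key] = (len(segs), d_mean, d_se)
        speeds = [segment_speed(s) for s in segs]
        s_mean, s_se = group_mean_se(speeds)
        speed_cells[key] = (s_mean, s_se, max(speeds))
    return BirdSummary(
        bird_id=bird_id,
        n_day_water=len(cells.get(("day", "water"), [])),
        n_night_water=len(cells.get(("night", "water"), [])),
        total_km=float(sum(s.distance_km for s in segments)),
        max_24h_km=max_24h_distance(segments),
        distance_cells=distance_cells,
        speed_cells=speed_cells,
    )


def summaries_to_frames(summaries: list[BirdSummary]):
    """Three tables: water-flight counts, distance cells, speed cells."""
    import pandas as pd

    t1 = pd.DataFrame(
        [
            {"bird_id": s.bird_id, "n_day_water": s.n_day_water, "n_night_water": s.n_night_water}
            for s in summaries
        ]
    )
    rows2, rows3 = [], []
    for s in summaries:
        r2 = {"bird_id": s.bird_id, "total_km": round(s.total_km, 2), "max_24h_km": round(s.max_24h_km, 2)}
        r3 = {"bird_id": s.bird_id}
        for phase in PHASES:
            for surf in SURFACES:
                key = f"{surf}_{phase}"
                cell = s.distance_cells.get((phase, surf))
                r2[f"dist_{key}_mean"] = round(cell[1], 2) if cell else None
                r2[f"dist_{key}_se"] = round(cell[2], 2) if cell else None
                sp = s.speed_cells.get((phase, surf))
                r3[f"speed_{key}_mean"] = round(sp[0], 2) if sp else None
                r3[f"speed_{key}_se"] = round(sp[1], 2) if sp else None
                r3[f"speed_{key}_max"] = round(sp[2], 2) if sp else None
        rows2.append(r2)
        rows3.append(r3)
    return t1, pd.DataFrame(rows2), pd.DataFrame(rows3)
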