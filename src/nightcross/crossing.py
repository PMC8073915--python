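"""Coastal departure points, crossing/detour geometry, and covariates.

A *departure point* is the last over-land fix before a bird either
launches a water crossing or reorients to detour around the waterbody.
Crossings are read directly off the classified track (maximal runs of
water segments); detours are land fixes at the coast where the route
ahead in the bird's optimal direction is blocked by water yet the
realized flight turns well away from that direction.

Each departure carries the covariates of the route-choice model: the
tailwind assistance at the departure fix, the water:land distance ratio
(crossing distance over the shortest land-constrained circumnavigation),
and whether the following flight segment was nocturnal.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import shapely
from shapely.geometry import LineString, Point

from .geo import destination_point, geodesic_km, initial_bearing
from .movement import LandWaterMask
from .tracks import GPSFix, TrackSegment
from .wind import WindGrid, assign_optimal_direction, tailwind

logger = logging.getLogger(__name__)

COASTAL_BUFFER_KM = 50.0
MIN_BLOCK_KM = 100.0
DETOUR_ANGLE_DEG = 60.0


class DepartureExclusion(Exception):
    """A departure that cannot enter the model, with the reason why."""


@dataclass
class Departure:
    """A coastal decision point with outcome and covariates."""

    bird_id: str
    fix: GPSFix
    waterbody: str
    decision: str  # "cross" | "detour"
    night: bool
    optimal_deg: float
    tailwind_ms: float | None = None
    cross_km: float | None = None
    land_km: float | None = None
    ratio: float | None = None
    excluded_reason: str | None = None


def _angle_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def _run_waterbody(run: list[TrackSegment], mask: LandWaterMask) -> str:
    """Polygon holding the majority of a water run's over-water km."""
    totals = {name: 0.0 for name in mask.names}
    for seg in run:
        per = mask.water_km_along(
            seg.start_fix.lat, seg.start_fix.lon, seg.end_fix.lat, seg.end_fix.lon,
            step_km=5.0,
        )
        for name, km in per.items():
            totals[name] += km
    return max(totals, key=totals.get)


def _ray_water_block_km(
    mask: LandWaterMask,
    waterbody: str,
    lat: float,
    lon: float,
    bearing: float,
    coastal_buffer_km: float,
    max_range_km: float = 2000.0,
    step_km: float = 5.0,
) -> float:
    """Length of the first water stretch on the ray from (lat, lon).

    Returns 0 when the polygon is not met within ``coastal_buffer_km``
    along the ray.
    """
    geom = mask.water_polygons[waterbody]
    n = int(max_range_km / step_km)
    d = np.arange(1, n + 1) * step_km
    pts = [destination_point(lat, lon, bearing, dk) for dk in d]
    inside = shapely.covers(geom, shapely.points([p[1] for p in pts], [p[0] for p in pts]))
    if not inside.any():
        return 0.0
    first = int(np.argmax(inside))
    if d[first] > coastal_buffer_km + step_km:
        return 0.0
    run_end = first
    while run_end < n and inside[run_end]:
        run_end += 1
    return float((run_end - first) * step_km)


def identify_departures(
    segments: list[TrackSegment],
    mask: LandWaterMask,
    destinations: dict[str, str],
    coastal_buffer_km: float = COASTAL_BUFFER_KM,
    min_block_km: float = MIN_BLOCK_KM,
    detour_angle_deg: float = DETOUR_ANGLE_DEG,
) -> list[Departure]:
    """Locate cross and detour departure points on classified tracks.

    Crossing events are maximal runs of water segments; their departure
    is the last land fix before the run.  Detour candidates are land
    fixes within ``coastal_buffer_km`` of a water polygon that blocks
    the optimal direction for at least ``min_block_km``, where the
    realized next bearing deviates from the optimal by at least
    ``detour_angle_deg``.  When both patterns match one fix the crossing
    wins (actual water entry dominates).  Consecutive detour fixes at
    the same waterbody collapse onto the first.
    """
    out: list[Departure] = []
    by_bird: dict[str, list[TrackSegment]] = {}
    for s in segments:
        if s.surface is None:
            raise ValueError("segments must be surface-classified first")
        by_bird.setdefault(s.bird_id, []).append(s)

    for bird_id, segs in by_bird.items():
        if bird_id not in destinations or destinations[bird_id] is None:
            raise ValueError(f"no destination known for bird {bird_id}")
        dest = destinations[bird_id]
        segs = sorted(segs, key=lambda s: s.start_fix.t)

        cross_fix_times = set()
        i = 0
        while i < len(segs):
            if segs[i].surface == "water":
                j = i
                while j < len(segs) and segs[j].surface == "water":
                    j += 1
                run = segs[i:j]
                waterbody = _run_waterbody(run, mask)
                dep_fix = run[0].start_fix
                out.append(
                    Departure(
                        bird_id=bird_id,
                        fix=dep_fix,
                        waterbody=waterbody,
                        decision="cross",
                        night=run[0].phase == "night",
                        optimal_deg=assign_optimal_direction(waterbody, dest),
                    )
                )
                cross_fix_times.add(dep_fix.t)
                i = j
            else:
                i += 1

        last_detour: tuple[str, int] | None = None
        for k, seg in enumerate(segs):
            if seg.surface != "land":
                last_detour = None
                continue
            f = seg.start_fix
            if f.t in cross_fix_times or not mask.on_land(f.lat, f.lon):
                continue
            dists = mask.distance_to_water_km(f.lat, f.lon)
            near = {n: d for n, d in dists.items() if d <= coastal_buffer_km}
            if not near:
                last_detour = None
                continue
            if seg.distance_km <= 0:
                continue
            realized = initial_bearing(f.lat, f.lon, seg.end_fix.lat, seg.end_fix.lon)
            hit = None
            for name in sorted(near, key=near.get):
                opt = assign_optimal_direction(name, dest)
                block = _ray_water_block_km(
                    mask, name, f.lat, f.lon, opt, coastal_buffer_km
                )
                if block >= min_block_km and _angle_diff(realized, opt) >= detour_angle_deg:
                    hit = (name, opt)
                    break
            if hit is None:
                last_detour = None
                continue
            if last_detour == (hit[0], k - 1):
                last_detour = (hit[0], k)  # same coastal dawdle, keep first only
                continue
            out.append(
                Departure(
                    bird_id=bird_id,
                    fix=f,
                    waterbody=hit[0],
                    decision="detour",
                    night=seg.phase == "night",
                    optimal_deg=hit[1],
                )
            )
            last_detour = (hit[0], k)
    out.sort(key=lambda d: (d.bird_id, d.fix.t))
    return out


def barrier_extent_km(
    mask: LandWaterMask,
    waterbody: str,
    lat: float,
    lon: float,
    bearing: float,
    max_range_km: float = 3000.0,
    step_km: float = 5.0,
) -> tuple[float, float]:
    """(entry, exit) distance of a waterbody along a ray, in km.

    Entry is where the ray first meets the polygon, exit where it last
    leaves it within ``max_range_km``.  Raises ValueError when the ray
    never meets the polygon.
    """
    geom = mask.water_polygons[waterbody]
    n = int(max_range_km / step_km)
    d = np.arange(1, n + 1) * step_km
    pts = [destination_point(lat, lon, bearing, dk) for dk in d]
    inside = shapely.covers(geom, shapely.points([p[1] for p in pts], [p[0] for p in pts]))
    if not inside.any():
        raise ValueError(f"ray at {bearing} deg never meets {waterbody}")
    idx = np.flatnonzero(inside)
    return float(d[idx[0]]), float(d[idx[-1]])


def crossing_distance(
    departure: Departure,
    subsequent_fixes: list[GPSFix],
    mask: LandWaterMask,
) -> tuple[float, GPSFix]:
    """Geodesic km from the departure fix to the first far-side land fix.

    "Far side" means beyond the waterbody in the migration direction:
    the fix's along-track projection on the departure's optimal bearing
    must reach past the barrier's exit edge on that bearing.  The bird's
    motion from the fix must also continue within 90 degrees of the
    optimal bearing (moving away from the waterbody).  For detours this
    measures the *hypothetical* crossing the bird declined.  Raises
    :class:`DepartureExclusion` when no qualifying fix exists.
    """
    f = departure.fix
    try:
        _, d_far = barrier_extent_km(
            mask, departure.waterbody, f.lat, f.lon, departure.optimal_deg
        )
    except ValueError as exc:
        raise DepartureExclusion(
            f"bird {departure.bird_id} at {f.t}: {exc}"
        ) from None
    cand = sorted((c for c in subsequent_fixes if c.t > f.t), key=lambda c: c.t)
    for idx, c in enumerate(cand):
        if not mask.on_land(c.lat, c.lon):
            continue
        dist = float(geodesic_km(f.lat, f.lon, c.lat, c.lon))
        if dist <= 0:
            continue
        along = dist * math.cos(
            math.radians(
                _angle_diff(
                    initial_bearing(f.lat, f.lon, c.lat, c.lon), departure.optimal_deg
                )
            )
        )
        if along < d_far:
            continue
        nxt = cand[idx + 1] if idx + 1 < len(cand) else None
        if nxt is not None and (c.lat, c.lon) != (nxt.lat, nxt.lon):
            away = initial_bearing(c.lat, c.lon, nxt.lat, nxt.lon)
            if _angle_diff(away, departure.optimal_deg) > 90.0:
                continue
        return dist, c
    raise DepartureExclusion(
        f"bird {departure.bird_id} at {f.t}: no land fix on the far side of "
        f"{departure.waterbody}"
    )


def _polygon_vertices(geom) -> list[tuple[float, float]]:
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    verts = []
    for p in polys:
        verts.extend(p.exterior.coords[:-1])
        for ring in p.interiors:
            verts.extend(ring.coords[:-1])
    return verts


def circumnavigation_distance(p_from, p_to, mask: LandWaterMask) -> float:
    """Shortest land-constrained polyline between two land points, in km.

    The path is the minimum-weight route on a visibility graph whose
    nodes are the endpoints plus every water-polygon vertex and whose
    edges are the straight lon/lat connections that do not enter water;
    edges are weighted by great-circle length.  ``p_from``/``p_to`` are
    (lat, lon) pairs.  Raises ValueError when no over-land path exists.
    """
    (lat_a, lon_a), (lat_b, lon_b) = p_from, p_to
    for lab, (la, lo) in (("p_from", p_from), ("p_to", p_to)):
        if not mask.on_land(la, lo):
            raise ValueError(f"{lab} ({la}, {lo}) is not on land")
    if not mask.water_polygons:
        return float(geodesic_km(lat_a, lon_a, lat_b, lon_b))
    # erode obstacles slightly so boundary-hugging edges remain legal
    obstacle = shapely.unary_union(
        [g.buffer(-1e-9) for g in mask.water_polygons.values()]
    )
    nodes: list[tuple[float, float]] = [(lon_a, lat_a), (lon_b, lat_b)]
    for geom in mask.water_polygons.values():
        nodes.extend(_polygon_vertices(geom))
    lines = [
        LineString([nodes[i], nodes[j]])
        for i, j in itertools.combinations(range(len(nodes)), 2)
    ]
    blocked = shapely.intersects(obstacle, lines)
    g = nx.Graph()
    for (i, j), bad in zip(itertools.combinations(range(len(nodes)), 2), blocked):
        if bad:
            continue
        (xi, yi), (xj, yj) = nodes[i], nodes[j]
        g.add_edge(i, j, weight=float(geodesic_km(yi, xi, yj, xj)))
    try:
        return float(nx.dijkstra_path_length(g, 0, 1))
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        raise ValueError("no land-constrained path between the points") from None


def water_land_ratio(cross_km: float, land_km: float) -> float:
    """Water-crossing distance over circumnavigation distance.

    Values below 1 mean the crossing is the shorter option.
    """
    if cross_km <= 0 or land_km <= 0:
        raise ValueError("distances must be positive")
    return cross_km / land_km


def scale_center(x) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (divisor n-1)."""
    x = np.asarray(list(x), float)
    if x.size < 2:
        raise ValueError("scale_center needs at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("scale_center undefined for constant input")
    return (x - x.mean()) / sd


def build_departure_table(
    departures: list[Departure],
    fixes_by_bird: dict[str, list[GPSFix]],
    mask: LandWaterMask,
    wind: WindGrid,
) -> tuple[list[Departure], list[Departure]]:
    """Fill covariates for every departure; split kept from excluded.

    Tailwind is interpolated at the departure fix; the crossing distance
    is measured to the first qualifying far-side fix and the
    circumnavigation distance over the visibility graph between the same
    endpoints.  Departures without a usable far-side fix (or land path)
    are excluded with a logged reason, never silently dropped.
    """
    kept, excluded = [], []
    for dep in departures:
        u, v = wind.interp_uv(dep.fix.lat, dep.fix.lon, dep.fix.t)
        dep.tailwind_ms = float(tailwind(u, v, dep.optimal_deg))
        try:
            cross_km, far_fix = crossing_distance(
                dep, fixes_by_bird.get(dep.bird_id, []), mask
            )
            land_km = circumnavigation_distance(
                (dep.fix.lat, dep.fix.lon), (far_fix.lat, far_fix.lon), mask
            )
        except (DepartureExclusion, ValueError) as exc:
            dep.excluded_reason = str(exc)
            logger.warning("departure excluded: %s", exc)
            excluded.append(dep)
            continue
        dep.cross_km = cross_km
        dep.land_km = land_km
        dep.ratio = water_land_ratio(cross_km, land_km)
        kept.append(dep)
    return kept, excluded


def departures_to_frame(departures: list[Departure]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "bird_id": d.bird_id,
                "time": d.fix.t.isoformat(),
                "lat": d.fix.lat,
                "lon": d.fix.lon,
                "waterbody": d.waterbody,
                "decision": d.decision,
                "night": int(d.night),
                "optimal_deg": d.optimal_deg,
                "tailwind_ms": d.tailwind_ms,
                "cross_km": d.cross_km,
                "land_km": d.land_km,
                "ratio": d.ratio,
                "excluded_reason": d.excluded_reason,
            }
            for d in departures
        ],
        columns=[
            "bird_id", "time", "lat", "lon", "waterbody", "decision", "night",
            "optimal_deg", "tailwind_ms", "cross_km", "land_km", "ratio",
            "excluded_reason",
        ],
    )
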