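"""Independent oracles used only by the tests.

These deliberately re-derive quantities along different routes from the
package implementation: a low-precision Astronomical Almanac solar
position (Michalsky-style) with bisection for rise/set events, a
minute-grid integration of the daylight indicator, and a land-only
lattice shortest path with line-of-sight smoothing.
"""

from __future__ import annotations

import math
from datetime import datetime, timedelta, timezone

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as sp_dijkstra


# --- solar altitude via the Astronomical Almanac low-precision formulae ----

def almanac_sun_altitude(lat: float, lon: float, dt: datetime) -> float:
    """Apparent solar altitude (deg) from the Almanac low-precision series."""
    dt = dt.astimezone(timezone.utc)
    # days from J2000.0
    n = (dt - datetime(2000, 1, 1, 12, tzinfo=timezone.utc)).total_seconds() / 86400.0
    L = (280.460 + 0.9856474 * n) % 360.0
    g = math.radians((357.528 + 0.9856003 * n) % 360.0)
    lam = math.radians(L + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g))
    eps = math.radians(23.439 - 4e-7 * n)
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))
    dec = math.asin(math.sin(eps) * math.sin(lam))
    ut_hours = dt.hour + dt.minute / 60.0 + dt.second / 3600.0
    # sidereal time: 6.697375 + 0.0657098242*n0 + 1.00273790935*UT, n0 at 0h UT
    n0 = n - ut_hours / 24.0
    gmst = (6.697375 + 0.0657098242 * n0 + 1.00273790935 * ut_hours) % 24.0
    lmst = math.radians((gmst * 15.0 + lon) % 360.0)
    ha = lmst - ra
    alt = math.asin(
        math.sin(math.radians(lat)) * math.sin(dec)
        + math.cos(math.radians(lat)) * math.cos(dec) * math.cos(ha)
    )
    return math.degrees(alt)


def almanac_event(lat: float, lon: float, date, which: str) -> datetime | None:
    """Sunrise/sunset (altitude crossing of -0.833 deg) by minute scan and
    bisection; None in polar regimes."""
    day0 = datetime(date.year, date.month, date.day, tzinfo=timezone.utc)
    # coarse 2-min scan for the sign change of (alt + 0.833)
    ts = [day0 + timedelta(minutes=2 * i) for i in range(721)]
    alts = np.array([almanac_sun_altitude(lat, lon, t) for t in ts]) + 0.8333
    for i in range(len(ts) - 1):
        a, b = alts[i], alts[i + 1]
        rising = a < 0 <= b
        setting = a >= 0 > b
        if (which == "sunrise" and rising) or (which == "sunset" and setting):
            lo, hi = ts[i], ts[i + 1]
            for _ in range(20):
                mid = lo + (hi - lo) / 2
                am = almanac_sun_altitude(lat, lon, mid) + 0.8333
                if (am >= 0) == (which == "sunset"):
                    lo = mid
                else:
                    hi = mid
            return lo + (hi - lo) / 2
    return None


# --- minute-grid daylight integration --------------------------------------

def minute_grid_daylight(segment, sunrise_near, sunset_near) -> float:
    """Brute-force minutes of daylight using the endpoint event times."""
    t0 = segment.start_fix.t
    t1 = segment.end_fix.t
    n_min = int(round((t1 - t0).total_seconds() / 60.0))
    if segment.phase == "day":
        rise, r_reg = sunrise_near(segment.start_fix.lat, segment.start_fix.lon, t0)
        set_, s_reg = sunset_near(segment.end_fix.lat, segment.end_fix.lon, t1)
        count = 0
        for m in range(n_min):
            t = t0 + timedelta(minutes=m + 0.5)
            after_rise = r_reg == "polar_day" or (r_reg == "normal" and t >= rise)
            before_set = s_reg == "polar_day" or (s_reg == "normal" and t <= set_)
            count += after_rise and before_set
        return float(count)
    set_, s_reg = sunset_near(segment.start_fix.lat, segment.start_fix.lon, t0)
    rise, r_reg = sunrise_near(segment.end_fix.lat, segment.end_fix.lon, t1)
    count = 0
    for m in range(n_min):
        t = t0 + timedelta(minutes=m + 0.5)
        evening = s_reg == "polar_day" or (s_reg == "normal" and t <= set_)
        morning = r_reg == "polar_day" or (r_reg == "normal" and t >= rise)
        count += evening or morning
    return float(count)


# --- land-only lattice shortest path ---------------------------------------

_MOVES = [
    (1, 0), (0, 1), (-1, 0), (0, -1),
    (1, 1), (1, -1), (-1, 1), (-1, -1),
    (1, 2), (2, 1), (-1, 2), (-2, 1), (1, -2), (2, -1), (-1, -2), (-2, -1),
]


def lattice_path_km(p_from, p_to, water_geoms, geodesic_km, n_grid: int = 90) -> float:
    """Dijkstra on a land-only lattice, then line-of-sight smoothing.

    ``p_from``/``p_to`` are (lat, lon); ``water_geoms`` shapely polygons.
    """
    (lat_a, lon_a), (lat_b, lon_b) = p_from, p_to
    lats = [lat_a, lat_b]
    lons = [lon_a, lon_b]
    for g in water_geoms:
        x0, y0, x1, y1 = g.bounds
        lats += [y0, y1]
        lons += [x0, x1]
    pad = 1.0
    la0, la1 = min(lats) - pad, max(lats) + pad
    lo0, lo1 = min(lons) - pad, max(lons) + pad
    glat = np.linspace(la0, la1, n_grid)
    glon = np.linspace(lo0, lo1, n_grid)
    # snap endpoints onto the grid
    ia = (np.abs(glat - lat_a).argmin(), np.abs(glon - lon_a).argmin())
    ib = (np.abs(glat - lat_b).argmin(), np.abs(glon - lon_b).argmin())
    glat[ia[0]], glon[ia[1]] = lat_a, lon_a
    glat[ib[0]], glon[ib[1]] = lat_b, lon_b

    union = shapely.unary_union(list(water_geoms))
    LA, LO = np.meshgrid(glat, glon, indexing="ij")
    water = shapely.covers(union, shapely.points(LO.ravel(), LA.ravel())).reshape(LA.shape)

    def nid(i, j):
        return i * n_grid + j

    rows, cols, w = [], [], []
    for di, dj in _MOVES:
        i0 = np.arange(max(0, -di), min(n_grid, n_grid - di))
        j0 = np.arange(max(0, -dj), min(n_grid, n_grid - dj))
        I, J = np.meshgrid(i0, j0, indexing="ij")
        I2, J2 = I + di, J + dj
        ok = ~water[I, J] & ~water[I2, J2]
        # knight moves: also require the midpoint on land
        mid_lat = 0.5 * (glat[I] + glat[I2])
        mid_lon = 0.5 * (glon[J] + glon[J2])
        mid_water = shapely.covers(
            union, shapely.points(mid_lon.ravel(), mid_lat.ravel())
        ).reshape(I.shape)
        ok &= ~mid_water
        d = geodesic_km(glat[I][ok], glon[J][ok], glat[I2][ok], glon[J2][ok])
        rows.extend(nid(I[ok], J[ok]))
        cols.extend(nid(I2[ok], J2[ok]))
        w.extend(np.atleast_1d(d))
    n = n_grid * n_grid
    graph = coo_matrix(
        (np.array(w), (np.array(rows), np.array(cols))), shape=(n, n)
    ).tocsr()
    src, dst = nid(*ia), nid(*ib)
    dist, pred = sp_dijkstra(graph, indices=src, return_predecessors=True)
    if not np.isfinite(dist[dst]):
        raise ValueError("no lattice path")
    path = [dst]
    while path[-1] != src:
        path.append(pred[path[-1]])
    path = path[::-1]
    pts = [(glat[p // n_grid], glon[p % n_grid]) for p in path]

    def clear(p, q):
        f = np.linspace(0.0, 1.0, 60)
        ll = shapely.points(p[1] + f * (q[1] - p[1]), p[0] + f * (q[0] - p[0]))
        return not shapely.covers(union, ll).any()

    # greedy string pulling
    smooth = [pts[0]]
    i = 0
    while i < len(pts) - 1:
        j = len(pts) - 1
        while j > i + 1 and not clear(pts[i], pts[j]):
            j -= 1
        smooth.append(pts[j])
        i = j
    return float(
        sum(geodesic_km(a[0], a[1], b[0], b[1]) for a, b in zip(smooth, smooth[1:]))
    )
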