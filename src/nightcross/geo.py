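"""Great-circle geodesy on the sphere.

Distances use the haversine formula on a sphere of mean radius
6371.0088 km.  At the scale of continental migration tracks the
discrepancy against an ellipsoidal geodesic is below 0.5%, which is
immaterial relative to GPS fix spacing, so the simpler spherical model
is used throughout.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def geodesic_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between two points (degrees WGS84).

    Accepts scalars or broadcastable arrays; symmetric and non-negative.
    """
    phi1, lam1, phi2, lam2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards rounding for near-antipodal points
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing(lat1, lon1, lat2, lon2):
    """Forward azimuth at the first point, degrees clockwise from true north.

    Undefined for coincident or antipodal points, which raise ValueError.
    """
    tol = 1e-9  # degrees; only genuinely identical points are undefined
    dlon0 = abs((lon1 - lon2 + 180.0) % 360.0 - 180.0)
    if abs(lat1 - lat2) < tol and dlon0 < tol:
        raise ValueError("bearing undefined for coincident points")
    dlon180 = abs(abs((lon1 - lon2 + 180.0) % 360.0 - 180.0) - 180.0)
    if abs(lat1 + lat2) < tol and dlon180 < tol:
        raise ValueError("bearing undefined for antipodal points")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(lon2 - lon1)
    y = np.sin(dlam) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam)
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def destination_point(lat, lon, bearing_deg, distance_km):
    """Point reached travelling ``distance_km`` along ``bearing_deg``.

    Direct great-circle problem on the sphere; returns (lat, lon) degrees
    with lon normalised to [-180, 180).
    """
    delta = distance_km / EARTH_RADIUS_KM
    theta = np.radians(bearing_deg)
    phi1, lam1 = np.radians(lat), np.radians(lon)
    phi2 = np.arcsin(
        np.sin(phi1) * np.cos(delta) + np.cos(phi1) * np.sin(delta) * np.cos(theta)
    )
    lam2 = lam1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(phi1),
        np.cos(delta) - np.sin(phi1) * np.sin(phi2),
    )
    return float(np.degrees(phi2)), float((np.degrees(lam2) + 180.0) % 360.0 - 180.0)


def gc_points(lat1, lon1, lat2, lon2, n):
    """``n`` points spaced evenly along the great circle (inclusive of ends).

    Spherical linear interpolation; degenerate (coincident) endpoints
    return the start point repeated.
    """
    phi1, lam1, phi2, lam2 = map(np.radians, (lat1, lon1, lat2, lon2))
    v1 = np.array(
        [np.cos(phi1) * np.cos(lam1), np.cos(phi1) * np.sin(lam1), np.sin(phi1)]
    )
    v2 = np.array(
        [np.cos(phi2) * np.cos(lam2), np.cos(phi2) * np.sin(lam2), np.sin(phi2)]
    )
    omega = np.arccos(np.clip(v1 @ v2, -1.0, 1.0))
    f = np.linspace(0.0, 1.0, n)
    if omega < 1e-12:
        v = np.tile(v1, (n, 1))
    else:
        v = (
            np.sin((1 - f)[:, None] * omega) * v1[None, :]
            + np.sin(f[:, None] * omega) * v2[None, :]
        ) / np.sin(omega)
    lats = np.degrees(np.arcsin(np.clip(v[:, 2] / np.linalg.norm(v, axis=1), -1, 1)))
    lons = np.degrees(np.arctan2(v[:, 1], v[:, 0]))
    return lats, lons
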