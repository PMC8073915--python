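"""Gridded wind fields, tailwind assistance, and direction statistics.

Winds come as eastward (U) and northward (V) components on a regular
2.5-degree lat/lon grid at 6-hourly steps, the layout of surface-level
reanalysis products.  Interpolation is trilinear (bilinear in space,
linear in time).  *Tailwind assistance* is the wind vector projected on
an assumed optimal travel direction:

    Ta = u sin(theta) + v cos(theta),   theta = optimal bearing

positive when the wind flows along the optimal direction, negative for
headwind.  No airspeed enters the definition.

Direction convention throughout is the direction the wind blows
*toward*, clockwise from north (so a due-north wind with v > 0 has
direction 0); :func:`dir_from` converts to the meteorological "from"
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

GRID_SPACING_DEG = 2.5
GRID_STEP_HOURS = 6.0

#: assumed optimal crossing bearing per waterbody; the Gulf of Mexico
#: heading depends on the bird's breeding destination.  "sea" and "gulf"
#: are the two east-west water bands of the synthetic world, crossed due
#: north regardless of destination.
OPTIMAL_DIRECTIONS = {
    ("caribbean", None): 270.0,
    ("gulf_of_honduras", None): 315.0,
    ("gulf_of_mexico", "texas"): 315.0,
    ("gulf_of_mexico", "manitoba"): 0.0,
    ("gulf_of_mexico", "florida"): 45.0,
    ("sea", None): 0.0,
    ("gulf", None): 0.0,
}


@dataclass(frozen=True)
class WindSample:
    u: float
    v: float
    speed: float
    dir_toward: float  # degrees clockwise from north, [0, 360)
    direction_defined: bool = True


def _to_epoch_s(t) -> float:
    if isinstance(t, datetime):
        if t.tzinfo is None:
            t = t.replace(tzinfo=timezone.utc)
        return t.timestamp()
    return pd.Timestamp(t).timestamp()


class WindGrid:
    """U/V wind components on a (time, lat, lon) lattice."""

    def __init__(self, times, lats, lons, u, v):
        self.times = pd.DatetimeIndex(times)
        self.lats = np.asarray(lats, float)
        self.lons = np.asarray(lons, float)
        self.u = np.asarray(u, float)
        self.v = np.asarray(v, float)
        shape = (len(self.times), len(self.lats), len(self.lons))
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"U/V shapes {self.u.shape}/{self.v.shape} != axes {shape}")
        if np.any(np.diff(self.lats) <= 0) or np.any(np.diff(self.lons) <= 0):
            raise ValueError("lat/lon axes must be strictly ascending")
        dt = np.diff(self.times.asi8)
        if len(dt) and (np.any(dt <= 0) or np.any(dt != dt[0])):
            raise ValueError("times must be strictly increasing and equally spaced")
        self._t_s = np.array([_to_epoch_s(t) for t in self.times])
        self._interp_u = RegularGridInterpolator(
            (self._t_s, self.lats, self.lons), self.u, method="linear", bounds_error=True
        )
        self._interp_v = RegularGridInterpolator(
            (self._t_s, self.lats, self.lons), self.v, method="linear", bounds_error=True
        )

    # -- I/O -----------------------------------------------------------
    @classmethod
    def from_netcdf(cls, path) -> "WindGrid":
        import xarray as xr

        ds = xr.open_dataset(path)
        try:
            lat = ds["lat"].values
            lon = ds["lon"].values
            u = ds["uwnd"].transpose("time", "lat", "lon").values
            v = ds["vwnd"].transpose("time", "lat", "lon").values
            times = pd.DatetimeIndex(ds["time"].values)
        finally:
            ds.close()
        order_lat = np.argsort(lat)
        order_lon = np.argsort(lon)
        return cls(times, lat[order_lat], lon[order_lon],
                   u[:, order_lat][:, :, order_lon], v[:, order_lat][:, :, order_lon])

    def to_netcdf(self, path) -> None:
        import xarray as xr

        ds = xr.Dataset(
            {
                "uwnd": (("time", "lat", "lon"), self.u),
                "vwnd": (("time", "lat", "lon"), self.v),
            },
            coords={"time": self.times.tz_localize(None) if self.times.tz else self.times,
                    "lat": self.lats, "lon": self.lons},
        )
        # NetCDF3 so the file stays readable through the scipy backend
        ds.to_netcdf(path, format="NETCDF3_CLASSIC")

    @classmethod
    def from_csv(cls, path) -> "WindGrid":
        """Plain long-format dialect: columns time, lat, lon, u, v."""
        df = pd.read_csv(path, parse_dates=["time"])
        missing = {"time", "lat", "lon", "u", "v"} - set(df.columns)
        if missing:
            raise ValueError(f"wind CSV missing columns {sorted(missing)}")
        times = np.sort(df["time"].unique())
        lats = np.sort(df["lat"].unique())
        lons = np.sort(df["lon"].unique())
        shape = (len(times), len(lats), len(lons))
        if len(df) != shape[0] * shape[1] * shape[2]:
            raise ValueError("wind CSV is not a complete regular grid")
        df = df.sort_values(["time", "lat", "lon"])
        return cls(times, lats, lons,
                   df["u"].to_numpy().reshape(shape), df["v"].to_numpy().reshape(shape))

    def to_csv(self, path) -> None:
        tt, la, lo = np.meshgrid(np.arange(len(self.times)), self.lats, self.lons, indexing="ij")
        pd.DataFrame(
            {
                "time": self.times[tt.ravel()],
                "lat": la.ravel(),
                "lon": lo.ravel(),
                "u": self.u.ravel(),
                "v": self.v.ravel(),
            }
        ).to_csv(path, index=False)

    # -- queries -------------------------------------------------------
    def _check_bounds(self, lat, lon, t_s):
        for name, val, axis in (
            ("time", t_s, self._t_s),
            ("lat", lat, self.lats),
            ("lon", lon, self.lons),
        ):
            if not axis[0] <= val <= axis[-1]:
                raise ValueError(
                    f"query {name} outside wind grid envelope "
                    f"[{axis[0]}, {axis[-1]}]"
                )

    def interp_uv(self, lat: float, lon: float, t) -> tuple[float, float]:
        """Trilinearly interpolated (u, v) at a point and time."""
        t_s = _to_epoch_s(t)
        self._check_bounds(lat, lon, t_s)
        q = np.array([[t_s, lat, lon]])
        return float(self._interp_u(q)[0]), float(self._interp_v(q)[0])


def interp_uv(grid: WindGrid, lat: float, lon: float, t) -> tuple[float, float]:
    return grid.interp_uv(lat, lon, t)


def tailwind(u, v, optimal_deg) -> float:
    """Wind-support component (m/s) along the optimal travel bearing."""
    th = np.radians(optimal_deg)
    return u * np.sin(th) + v * np.cos(th)


def speed_dir(u: float, v: float) -> WindSample:
    """Wind speed and the bearing the wind blows toward."""
    speed = math.hypot(u, v)
    if speed == 0.0:
        return WindSample(u, v, 0.0, 0.0, direction_defined=False)
    return WindSample(u, v, speed, math.degrees(math.atan2(u, v)) % 360.0)


def components_from(speed: float, dir_toward: float) -> tuple[float, float]:
    th = math.radians(dir_toward)
    return speed * math.sin(th), speed * math.cos(th)


def dir_from(dir_toward: float) -> float:
    """Convert a "toward" bearing to the meteorological "from" convention."""
    return (dir_toward + 180.0) % 360.0


def assign_optimal_direction(waterbody: str, destination: str) -> float:
    """Assumed optimal crossing bearing for a waterbody and destination."""
    if (waterbody, None) in OPTIMAL_DIRECTIONS:
        return OPTIMAL_DIRECTIONS[(waterbody, None)]
    key = (waterbody, destination)
    if key not in OPTIMAL_DIRECTIONS:
        raise KeyError(
            f"no optimal direction for waterbody {waterbody!r}, destination {destination!r}"
        )
    return OPTIMAL_DIRECTIONS[key]


def _sector_index(bearing, n_sectors: int) -> np.ndarray:
    width = 360.0 / n_sectors
    return (np.floor((np.asarray(bearing, float) % 360.0 + width / 2.0) / width)).astype(int) % n_sectors


def bearing_histogram(bearings, n_sectors: int = 16) -> np.ndarray:
    """Counts per direction sector; sector 0 is centred on north."""
    if n_sectors < 1:
        raise ValueError("n_sectors must be positive")
    b = np.asarray(list(bearings), float)
    if b.size == 0:
        return np.zeros(n_sectors, int)
    return np.bincount(_sector_index(b, n_sectors), minlength=n_sectors)


def windrose_table(samples, n_sectors: int = 16, speed_breaks=(2.0, 4.0, 6.0, 8.0)) -> pd.DataFrame:
    """Sector x speed-class frequency table of wind samples.

    Rows are direction sectors (centre bearing in the index), columns the
    speed classes [0,b1), [b1,b2), ..., [bk,inf); frequencies sum to the
    sample count.  Samples with undefined direction (calm) land in the
    north sector by convention.
    """
    if n_sectors < 1:
        raise ValueError("n_sectors must be positive")
    breaks = [0.0, *speed_breaks, np.inf]
    cols = [f"[{breaks[i]:g},{breaks[i+1]:g})" for i in range(len(breaks) - 1)]
    width = 360.0 / n_sectors
    idx = [(i * width) % 360.0 for i in range(n_sectors)]
    table = pd.DataFrame(0, index=pd.Index(idx, name="sector_center_deg"), columns=cols)
    samples = list(samples)
    if not samples:
        return table
    sec = _sector_index([s.dir_toward for s in samples], n_sectors)
    cls = np.searchsorted(np.asarray(breaks[1:-1]), [s.speed for s in samples], side="right")
    for s_i, c_i in zip(sec, cls):
        table.iloc[s_i, c_i] += 1
    return table
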