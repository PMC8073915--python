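"""Sunrise/sunset computation and daylight overlap of 12-h track segments.

Solar event times come from the NOAA solar-position equations (the
algorithm behind the NOAA solar calculator, after Meeus), using the
conventional sunrise/sunset zenith of 90.833 degrees (34' refraction plus
16' solar semidiameter).  Accuracy is a fraction of a minute at
mid-latitudes, degrading gently toward the polar circles where the
event geometry itself becomes ill-conditioned.

GPS tags on fixed 12-h schedules sample flights whose light environment
drifts with season and latitude, so each nominal "night" segment can
contain real daylight near dawn and dusk.  :func:`daylight_overlap`
quantifies that: it evaluates sunrise/sunset at the segment's *endpoint*
locations (the bird's position is only known there) and clips the
daylight interval against the segment's time span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date as Date
from datetime import datetime, timedelta, timezone

SUNRISE_SUNSET_ZENITH_DEG = 90.833

_MIN = timedelta(minutes=1)


@dataclass(frozen=True)
class SolarTimes:
    """Sunrise/sunset (UTC) at one location on one calendar date.

    ``regime`` is ``"normal"`` when both events occur, ``"polar_day"``
    when the sun never sets, ``"polar_night"`` when it never rises; the
    polar regimes carry no event times.
    """

    date: Date
    lat: float
    lon: float
    sunrise_utc: datetime | None
    sunset_utc: datetime | None
    regime: str


def _julian_day(dt: datetime) -> float:
    """Julian day number including the time-of-day fraction (UT)."""
    y, m = dt.year, dt.month
    d = dt.day + (dt.hour + (dt.minute + dt.second / 60.0) / 60.0) / 24.0
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _solar_coords(jc: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (min) at Julian century jc."""
    gml = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    gma_r = math.radians(gma)
    eq_ctr = (
        math.sin(gma_r) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * gma_r) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * gma_r) * 0.000289
    )
    true_long = gml + eq_ctr
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega)
    obliq_r = math.radians(obliq)
    decl = math.degrees(math.asin(math.sin(obliq_r) * math.sin(math.radians(app_long))))
    var_y = math.tan(obliq_r / 2.0) ** 2
    gml_r = math.radians(gml)
    eqtime = 4.0 * math.degrees(
        var_y * math.sin(2 * gml_r)
        - 2 * ecc * math.sin(gma_r)
        + 4 * ecc * var_y * math.sin(gma_r) * math.cos(2 * gml_r)
        - 0.5 * var_y**2 * math.sin(4 * gml_r)
        - 1.25 * ecc**2 * math.sin(2 * gma_r)
    )
    return decl, eqtime


def _hour_angle_cos(lat: float, decl: float, zenith: float) -> float:
    lat_r, decl_r = math.radians(lat), math.radians(decl)
    denom = math.cos(lat_r) * math.cos(decl_r)
    if abs(denom) < 1e-12:
        return math.inf
    return (math.cos(math.radians(zenith)) - math.sin(lat_r) * math.sin(decl_r)) / denom


def sun_times(lat: float, lon: float, date: Date, zenith: float = SUNRISE_SUNSET_ZENITH_DEG) -> SolarTimes:
    """Sunrise and sunset (UTC) for a location and UTC calendar date.

    Valid for years 1950-2100.  The event times are refined once by
    re-evaluating the solar coordinates at the first-pass event time.
    """
    if not -90.0 <= lat <= 90.0:
        raise ValueError(f"latitude {lat} out of range")
    if not 1950 <= date.year <= 2100:
        raise ValueError(f"year {date.year} outside supported range 1950-2100")
    midnight = datetime(date.year, date.month, date.day, tzinfo=timezone.utc)

    def _events(guess_min: tuple[float, float]) -> tuple[float, float, float]:
        out = []
        cos_ha = 0.0
        for i, g in enumerate(guess_min):
            jc = (_julian_day(midnight) + g / 1440.0 - 2451545.0) / 36525.0
            decl, eqtime = _solar_coords(jc)
            cos_ha = _hour_angle_cos(lat, decl, zenith)
            if abs(cos_ha) > 1.0:
                return math.nan, math.nan, cos_ha
            ha = math.degrees(math.acos(cos_ha))
            noon = 720.0 - 4.0 * lon - eqtime
            out.append(noon - 4.0 * ha if i == 0 else noon + 4.0 * ha)
        return out[0], out[1], cos_ha

    # first pass from local solar noon, second from the event times themselves
    noon_guess = 720.0 - 4.0 * lon
    rise, set_, cos_ha = _events((noon_guess, noon_guess))
    if not math.isnan(rise):
        rise, set_, cos_ha = _events((rise, set_))
    if math.isnan(rise):
        regime = "polar_night" if cos_ha > 1.0 else "polar_day"
        return SolarTimes(date, lat, lon, None, None, regime)
    return SolarTimes(
        date,
        lat,
        lon,
        midnight + timedelta(minutes=rise),
        midnight + timedelta(minutes=set_),
        "normal",
    )


def _event_near(lat: float, lon: float, t: datetime, which: str) -> tuple[datetime | None, str]:
    """The sunrise or sunset instance nearest ``t``, searching ±1 day.

    Returns ``(event_time, regime)``; a polar regime (on the date of
    ``t``) yields ``(None, regime)``.
    """
    t = t.astimezone(timezone.utc)
    candidates: list[datetime] = []
    for dd in (-1, 0, 1):
        st = sun_times(lat, lon, (t + timedelta(days=dd)).date())
        if dd == 0 and st.regime != "normal":
            return None, st.regime
        ev = st.sunrise_utc if which == "sunrise" else st.sunset_utc
        if ev is not None:
            candidates.append(ev)
    if not candidates:
        return None, "polar"
    return min(candidates, key=lambda ev: abs(ev - t)), "normal"


def sunrise_near(lat: float, lon: float, t: datetime) -> tuple[datetime | None, str]:
    return _event_near(lat, lon, t, "sunrise")


def sunset_near(lat: float, lon: float, t: datetime) -> tuple[datetime | None, str]:
    return _event_near(lat, lon, t, "sunset")


def daylight_overlap(segment) -> float:
    """Minutes of daylight within a 12-h track segment.

    Day segments take the overlap of [t0, t1] with [sunrise at the start
    location, sunset at the end location]; night segments sum the
    evening daylight tail after t0 (until sunset at the start location)
    and the morning head before t1 (after sunrise at the end location).
    Each sunrise/sunset is the instance nearest the relevant endpoint
    time.  The result is always within [0, segment duration].

    Polar regimes contribute per endpoint: polar day counts as the full
    span on that side, polar night as zero.
    """
    t0 = segment.start_fix.t.astimezone(timezone.utc)
    t1 = segment.end_fix.t.astimezone(timezone.utc)
    dur = (t1 - t0) / _MIN
    if dur <= 0:
        return 0.0
    lat0, lon0 = segment.start_fix.lat, segment.start_fix.lon
    lat1, lon1 = segment.end_fix.lat, segment.end_fix.lon

    if segment.phase == "day":
        rise, r_reg = sunrise_near(lat0, lon0, t0)
        set_, s_reg = sunset_near(lat1, lon1, t1)
        lo = t0 if r_reg == "polar_day" else (t1 if r_reg == "polar_night" else max(t0, rise))
        hi = t1 if s_reg == "polar_day" else (t0 if s_reg == "polar_night" else min(t1, set_))
        return float(min(max((hi - lo) / _MIN, 0.0), dur))

    set_, s_reg = sunset_near(lat0, lon0, t0)
    rise, r_reg = sunrise_near(lat1, lon1, t1)
    if s_reg == "polar_day":
        evening = dur
    elif s_reg == "polar_night":
        evening = 0.0
    else:
        evening = min(max((set_ - t0) / _MIN, 0.0), dur)
    if r_reg == "polar_day":
        morning = dur
    elif r_reg == "polar_night":
        morning = 0.0
    else:
        morning = min(max((t1 - rise) / _MIN, 0.0), dur)
    return float(min(evening + morning, dur))
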