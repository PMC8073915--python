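import sys
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

sys.path.insert(0, str(Path(__file__).parent))

from nightcross import GPSFix, LandWaterMask, TagSchedule, TrackSegment, WindGrid


def utc(*args):
    return datetime(*args, tzinfo=timezone.utc)


@pytest.fixture
def cdt_schedule():
    return TagSchedule("B1", -5.0, ("0600", "1800"))


@pytest.fixture
def three_slot_schedule():
    return TagSchedule("B1", -5.0, ("0000", "0600", "1800"))


@pytest.fixture
def square_mask():
    """One 5x5-degree water square south of a second smaller one."""
    return LandWaterMask({"sq": box(-75.0, 10.0, -70.0, 15.0)})


@pytest.fixture
def flat_wind():
    """Constant (u, v) = (3, -4) grid spanning the synthetic domain."""
    lats = np.arange(0.0, 35.1, 2.5)
    lons = np.arange(-90.0, -59.9, 2.5)
    times = pd.date_range("2018-03-01", periods=120, freq="6h")
    shape = (len(times), len(lats), len(lons))
    return WindGrid(times, lats, lons, np.full(shape, 3.0), np.full(shape, -4.0))


def make_segment(
    lat0, lon0, lat1, lon1, t0=None, hours=12.0, phase="day", bird="B1"
):
    t0 = t0 or utc(2018, 3, 15, 11)
    f0 = GPSFix(bird, t0, lat0, lon0, slot="0600")
    f1 = GPSFix(bird, t0 + timedelta(hours=hours), lat1, lon1, slot="1800")
    from nightcross.geo import geodesic_km

    return TrackSegment(
        bird_id=bird,
        start_fix=f0,
        end_fix=f1,
        phase=phase,
        duration_h=hours,
        distance_km=float(geodesic_km(lat0, lon0, lat1, lon1)),
    )
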