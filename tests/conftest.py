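from datetime import date

import numpy as np
import pandas as pd
import pytest

from dwellsurv import (
    GeofenceParams,
    GeoPoint,
    GpsFix,
    RetentionParams,
    StudyWindow,
    UploadLog,
    Workplace,
)

TZ = "Asia/Taipei"


@pytest.fixture
def params() -> GeofenceParams:
    return GeofenceParams()


@pytest.fixture
def workplace() -> Workplace:
    return Workplace("w0", GeoPoint(25.04, 121.52))


@pytest.fixture
def window() -> StudyWindow:
    return StudyWindow(date(2018, 8, 1), date(2019, 3, 31))


def ts(day: str, hhmm: str) -> pd.Timestamp:
    return pd.Timestamp(f"{day} {hhmm}", tz=TZ)


def fixes_at(times, points, user_id="u0"):
    return [GpsFix(user_id, t, p) for t, p in zip(times, points)]


def make_trace(day, segments, workplace_point, far_point, user_id="u0"):
    """Build a 10-minute trace from (hhmm_start, hhmm_end, in_range) segments."""
    out = []
    for start, end, inr in segments:
        t = ts(day, start)
        stop = ts(day, end)
        while t <= stop:
            out.append(
                GpsFix(user_id, t, workplace_point if inr else far_point)
            )
            t = t + pd.Timedelta(minutes=10)
    return out


def upload_log(days, registration="2018-09-01", stream="passive", user_id="u0"):
    reg = pd.Timestamp(registration, tz=TZ)
    stamps = pd.DatetimeIndex(
        [reg + pd.Timedelta(days=int(d), hours=12) for d in sorted(set(days))]
    )
    return UploadLog(user_id, stream, stamps, reg)


@pytest.fixture
def retention_params() -> RetentionParams:
    return RetentionParams()
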