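"""GPS geofence dwell-time detection and daily work-hour accounting.

A work-hours app samples the phone's location every ~10 minutes and keeps a
set of registered workplaces (at most five). A work session is detected with a
hysteresis rule: the session *opens* once the device has been inside a 1-km
geofence around any workplace for a confirmed 30-minute run of fixes, and the
session start is assigned retroactively to the first in-range fix of that run.
The session *closes* at the last in-range fix preceding a 30-minute span spent
out of range (or a 30-minute hole in the trace). Out-of-range excursions whose
fix run spans less than the confirmation window do not split a session.

Sessions are then intersected with local calendar days to produce daily total
work hours, and overtime is the signed difference between GPS-measured total
hours and user-scheduled hours (regular plus on-call).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

EARTH_RADIUS_KM = 6371.0
#: Local timezone used for calendar-day splitting; the app's market is Taiwan.
DEFAULT_TZ = "Asia/Taipei"
MAX_WORKPLACES = 5


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeoPoint:
    """A WGS84 point in decimal degrees. Longitude is normalized to
    [-180, 180); latitude outside [-90, 90] is rejected."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise InputError(f"latitude {self.lat} outside [-90, 90]")
        lon = ((self.lon + 180.0) % 360.0) - 180.0
        object.__setattr__(self, "lon", lon)


@dataclass(frozen=True)
class GpsFix:
    user_id: str
    t: pd.Timestamp
    point: GeoPoint

    def __post_init__(self) -> None:
        if self.t.tzinfo is None:
            raise InputError("GPS fix timestamps must be timezone-aware")


@dataclass(frozen=True)
class Workplace:
    workplace_id: str
    point: GeoPoint


@dataclass(frozen=True)
class GeofenceParams:
    """Detection parameters.

    radius_km
        Geofence radius around each workplace; a fix exactly on the boundary
        counts as in range (closed ball).
    sample_interval_min
        Nominal GPS sampling period.
    confirm_min
        Hysteresis window: minutes of consecutive same-state fixes required
        to open or close a session.
    """

    radius_km: float = 1.0
    sample_interval_min: float = 10.0
    confirm_min: float = 30.0

    def __post_init__(self) -> None:
        if min(self.radius_km, self.sample_interval_min, self.confirm_min) <= 0:
            raise ConfigurationError("geofence parameters must be positive")
        if self.confirm_min < self.sample_interval_min:
            raise ConfigurationError(
                "confirm_min must be at least sample_interval_min"
            )


@dataclass(frozen=True)
class WorkSession:
    """A detected presence interval at the workplace.

    ``open_at_end`` marks a session that was still open when the trace ended;
    it is closed at the last observed in-range fix.
    """

    user_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    open_at_end: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError("session start must precede end")

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass(frozen=True)
class DailyWorkRecord:
    user_id: str
    date: date
    total_hours: float
    scheduled_hours: float
    overtime_hours: float

    def __post_init__(self) -> None:
        if abs(self.overtime_hours - (self.total_hours - self.scheduled_hours)) > 1e-9:
            raise InputError("overtime_hours must equal total minus scheduled")


# ---------------------------------------------------------------------------
# Distance
# ---------------------------------------------------------------------------

def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, in km (haversine formula,
    spherical Earth of radius 6371 km)."""
    return float(
        _haversine_km_arrays(
            np.asarray(a.lat), np.asarray(a.lon), np.asarray(b.lat), np.asarray(b.lon)
        )
    )


def _haversine_km_arrays(lat1, lon1, lat2, lon2):
    """Vectorized haversine on degree arrays (broadcasting)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.minimum(1.0, np.sqrt(h)))


# ---------------------------------------------------------------------------
# Range test
# ---------------------------------------------------------------------------

def fix_in_range(
    fix: GpsFix,
    workplaces: Sequence[Workplace],
    params: GeofenceParams = GeofenceParams(),
) -> tuple[bool, str]:
    """Is a fix within the geofence of any workplace?

    Returns ``(in_range, nearest_workplace_id)``; distance ties are broken by
    registration order. The boundary (distance exactly equal to the radius)
    counts as in range.
    """
    if not workplaces:
        raise ConfigurationError("at least one workplace must be registered")
    if len(workplaces) > MAX_WORKPLACES:
        raise ConfigurationError(f"at most {MAX_WORKPLACES} workplaces per user")
    d = np.array([haversine_km(fix.point, w.point) for w in workplaces])
    i = int(np.argmin(d))
    return bool(d[i] <= params.radius_km), workplaces[i].workplace_id


def _in_range_flags(
    lats: np.ndarray,
    lons: np.ndarray,
    workplaces: Sequence[Workplace],
    radius_km: float,
) -> np.ndarray:
    if not workplaces:
        raise ConfigurationError("at least one workplace must be registered")
    if len(workplaces) > MAX_WORKPLACES:
        raise ConfigurationError(f"at most {MAX_WORKPLACES} workplaces per user")
    dmin = np.full(lats.shape, np.inf)
    for w in workplaces:
        d = _haversine_km_arrays(lats, lons, w.point.lat, w.point.lon)
        dmin = np.minimum(dmin, d)
    return dmin <= radius_km


# ---------------------------------------------------------------------------
# Session detection
# ---------------------------------------------------------------------------

def detect_sessions(
    trace: Sequence[GpsFix],
    workplaces: Sequence[Workplace],
    params: GeofenceParams = GeofenceParams(),
) -> list[WorkSession]:
    """Run the hysteresis state machine over a single user's sorted trace.

    Opening: the first maximal run of in-range fixes (no out-of-range fix and
    no >= confirm_min hole inside) whose first-to-last span reaches
    ``confirm_min`` opens a session at the run's first fix. Closing: a run of
    out-of-range fixes spanning >= confirm_min, or a hole in the trace of
    >= confirm_min, closes the session at the last in-range fix before it.
    """
    if not trace:
        return []
    user_ids = {f.user_id for f in trace}
    if len(user_ids) > 1:
        raise InputError("detect_sessions expects a single user's trace")
    times = np.array([f.t.value for f in trace], dtype=np.int64)  # ns since epoch
    if np.any(np.diff(times) <= 0):
        raise InputError("trace timestamps must be strictly increasing")
    lats = np.array([f.point.lat for f in trace])
    lons = np.array([f.point.lon for f in trace])
    flags = _in_range_flags(lats, lons, workplaces, params.radius_km)
    user_id = trace[0].user_id
    raw = _sessions_from_flags(times, flags, params.confirm_min)
    return [
        WorkSession(user_id, pd.Timestamp(s, unit="ns", tz=trace[0].t.tz),
                    pd.Timestamp(e, unit="ns", tz=trace[0].t.tz), open_at_end=fl)
        for s, e, fl in raw
    ]


def _sessions_from_flags(
    times_ns: np.ndarray, in_range: np.ndarray, confirm_min: float
) -> list[tuple[int, int, bool]]:
    """Core state machine on (timestamp, in_range) pairs.

    Returns (start_ns, end_ns, open_at_end) triples.
    """
    confirm_ns = int(round(confirm_min * 60 * 1e9))
    sessions: list[tuple[int, int, bool]] = []
    is_open = False
    cand_start: int | None = None  # first fix of candidate in-range run
    sess_start = 0
    last_in = 0  # last in-range fix while open
    out_start: int | None = None  # first out-of-range fix since last_in
    prev_t: int | None = None

    for t, inr in zip(times_ns.tolist(), in_range.tolist()):
        hole = prev_t is not None and (t - prev_t) >= confirm_ns
        if is_open:
            if hole:
                sessions.append((sess_start, last_in, False))
                is_open = False
                out_start = None
                cand_start = t if inr else None
            elif inr:
                last_in = t
                out_start = None
            else:
                if out_start is None:
                    out_start = t
                if t - out_start >= confirm_ns:
                    sessions.append((sess_start, last_in, False))
                    is_open = False
                    out_start = None
                    cand_start = None
        else:
            if hole:
                cand_start = t if inr else None
            elif inr:
                if cand_start is None:
                    cand_start = t
                if t - cand_start >= confirm_ns:
                    is_open = True
                    sess_start = cand_start
                    last_in = t
                    out_start = None
                    cand_start = None
            else:
                cand_start = None
        prev_t = t

    if is_open:
        sessions.append((sess_start, last_in, True))
    return sessions


# ---------------------------------------------------------------------------
# Daily aggregation and overtime
# ---------------------------------------------------------------------------

def daily_work_hours(
    sessions: Iterable[WorkSession], day: date, tz: str = DEFAULT_TZ
) -> float:
    """Total in-session hours intersecting one local calendar day.

    Sessions crossing midnight contribute only the part falling on ``day``.
    """
    day_start = pd.Timestamp(day, tz=tz)
    day_end = day_start + timedelta(days=1)
    total = 0.0
    for s in sessions:
        lo = max(s.start, day_start)
        hi = min(s.end, day_end)
        if hi > lo:
            total += (hi - lo).total_seconds() / 3600.0
    return total


def overtime(total_hours: float, scheduled_hours: float) -> float:
    """Signed overtime: GPS-measured total hours minus scheduled (regular +
    on-call) hours. Not clamped at zero; undertime is negative."""
    if total_hours < 0 or scheduled_hours < 0:
        raise InputError("hours must be non-negative")
    return total_hours - scheduled_hours


def daily_records(
    sessions: Sequence[WorkSession],
    scheduled_hours: float | Mapping[date, float] = 0.0,
    tz: str = DEFAULT_TZ,
) -> list[DailyWorkRecord]:
    """Build one DailyWorkRecord per local calendar day touched by a user's
    sessions. ``scheduled_hours`` may be a constant or a per-date mapping
    (missing dates default to 0)."""
    if not sessions:
        return []
    user_id = sessions[0].user_id
    days: set[date] = set()
    for s in sessions:
        d = s.start.tz_convert(tz).date()
        stop = s.end.tz_convert(tz).date()
        while d <= stop:
            days.add(d)
            d = d + timedelta(days=1)
    records = []
    for d in sorted(days):
        total = daily_work_hours(sessions, d, tz)
        if isinstance(scheduled_hours, Mapping):
            sched = float(scheduled_hours.get(d, 0.0))
        else:
            sched = float(scheduled_hours)
        records.append(DailyWorkRecord(user_id, d, total, sched, overtime(total, sched)))
    return records


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_trace_csv(path) -> pd.DataFrame:
    """Read a GPS trace CSV with columns user_id,timestamp,lat,lon
    (ISO-8601 timestamps with offset)."""
    df = pd.read_csv(path, dtype={"user_id": str})
    missing = {"user_id", "timestamp", "lat", "lon"} - set(df.columns)
    if missing:
        raise InputError(f"trace CSV missing columns: {sorted(missing)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df.sort_values(["user_id", "timestamp"], kind="stable").reset_index(drop=True)


def read_workplaces_csv(path) -> pd.DataFrame:
    """Read workplace registrations: user_id,workplace_id,lat,lon; at most
    five per user."""
    df = pd.read_csv(path, dtype={"user_id": str, "workplace_id": str})
    missing = {"user_id", "workplace_id", "lat", "lon"} - set(df.columns)
    if missing:
        raise InputError(f"workplace CSV missing columns: {sorted(missing)}")
    counts = df.groupby("user_id").size()
    over = counts[counts > MAX_WORKPLACES]
    if len(over):
        raise ConfigurationError(
            f"users with more than {MAX_WORKPLACES} workplaces: {list(over.index)}"
        )
    return df


def sessions_from_frames(
    trace: pd.DataFrame,
    workplaces: pd.DataFrame,
    params: GeofenceParams = GeofenceParams(),
    tz: str = DEFAULT_TZ,
) -> list[WorkSession]:
    """Detect sessions for every user present in a trace frame."""
    out: list[WorkSession] = []
    wp_by_user = {
        uid: [
            Workplace(str(r.workplace_id), GeoPoint(float(r.lat), float(r.lon)))
            for r in grp.itertuples()
        ]
        for uid, grp in workplaces.groupby("user_id")
    }
    for uid, grp in trace.groupby("user_id"):
        if uid not in wp_by_user:
            raise ConfigurationError(f"user {uid} has a trace but no workplace")
        times = grp["timestamp"].astype("int64").to_numpy()
        if np.any(np.diff(times) <= 0):
            raise InputError(f"trace of user {uid} is not strictly increasing")
        flags = _in_range_flags(
            grp["lat"].to_numpy(), grp["lon"].to_numpy(),
            wp_by_user[uid], params.radius_km,
        )
        for s, e, fl in _sessions_from_flags(times, flags, params.confirm_min):
            out.append(
                WorkSession(
                    str(uid),
                    pd.Timestamp(s, unit="ns", tz="UTC").tz_convert(tz),
                    pd.Timestamp(e, unit="ns", tz="UTC").tz_convert(tz),
                    open_at_end=fl,
                )
            )
    return out


def sessions_to_frame(sessions: Sequence[WorkSession]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "user_id": [s.user_id for s in sessions],
            "start": [s.start.isoformat() for s in sessions],
            "end": [s.end.isoformat() for s in sessions],
            "duration_min": [s.duration_min for s in sessions],
        }
    )


def daily_to_frame(records: Sequence[DailyWorkRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "user_id": [r.user_id for r in records],
            "date": [r.date.isoformat() for r in records],
            "total_hours": [r.total_hours for r in records],
            "scheduled_hours": [r.scheduled_hours for r in records],
            "overtime_hours": [r.overtime_hours for r in records],
        }
    )
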