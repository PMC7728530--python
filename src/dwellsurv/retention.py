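"""User-retention (churn) events from upload logs.

Retention of an app user is defined per data stream (passive sensor uploads
vs active survey submissions): retention stops on the first date opening a
28-day period in which no data of that stream were uploaded. A user whose
observation window ends without such a completed silent period is right-
censored at the study cutoff. Durations are whole days since registration
(day 0 = the registration date).

Cohort inclusion mirrors the deployment's rules: users must provide
demographics, and must have uploaded something within the first 28 days of
registration ("successful installation").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

Stream = Literal["passive", "active"]
STREAMS: tuple[Stream, Stream] = ("passive", "active")

OCCUPATIONS = (
    "resident_physician",
    "visiting_staff",
    "medical_student",
    "nurse",
    "other",
)
PLATFORMS = ("Android", "iOS")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RetentionParams:
    """gap_days: silence length defining churn; install_window_days: window
    after registration in which any upload counts as successful installation;
    churn_anchor: whether the churn date is the last upload day (default) or
    the first silent day (last upload + 1)."""

    gap_days: int = 28
    install_window_days: int = 28
    churn_anchor: Literal["last_upload", "gap_start"] = "last_upload"

    def __post_init__(self) -> None:
        if self.gap_days <= 0 or self.install_window_days <= 0:
            raise ConfigurationError("gap_days and install_window_days must be > 0")
        if self.churn_anchor not in ("last_upload", "gap_start"):
            raise ConfigurationError(f"unknown churn_anchor {self.churn_anchor!r}")


@dataclass(frozen=True)
class StudyWindow:
    start: date
    cutoff: date

    def __post_init__(self) -> None:
        if self.start >= self.cutoff:
            raise ConfigurationError("study start must precede cutoff")


@dataclass(frozen=True)
class Covariates:
    platform: str
    occupation: str
    age: float
    gender: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise InputError(f"unknown platform {self.platform!r}")
        if self.occupation not in OCCUPATIONS:
            raise InputError(f"unknown occupation {self.occupation!r}")


@dataclass(frozen=True)
class UploadLog:
    """All upload timestamps of one user in one stream, with the user's
    registration timestamp. Timestamps must be sorted and >= registration."""

    user_id: str
    stream: Stream
    timestamps: pd.DatetimeIndex
    registration: pd.Timestamp

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        object.__setattr__(self, "timestamps", ts)
        if len(ts):
            if not ts.is_monotonic_increasing:
                raise InputError("upload timestamps must be sorted ascending")
            if ts[0] < self.registration:
                raise InputError("uploads cannot precede registration")


@dataclass(frozen=True)
class RetentionRecord:
    user_id: str
    stream: Stream
    duration_days: int
    event: int
    covariates: Covariates

    def __post_init__(self) -> None:
        if self.event not in (0, 1):
            raise InputError("event must be 0 or 1")
        if self.duration_days < 0:
            raise InputError("duration_days must be >= 0")


# ---------------------------------------------------------------------------
# Day arithmetic
# ---------------------------------------------------------------------------

def _day_offsets(log: UploadLog) -> np.ndarray:
    """Whole-day offsets of uploads from the registration date, by local
    calendar date (the log's timestamps and registration share a timezone)."""
    reg_day = log.registration.normalize()
    days = (log.timestamps.normalize() - reg_day).days
    return np.unique(np.asarray(days, dtype=np.int64))


def _cutoff_day(log: UploadLog, window: StudyWindow) -> int:
    reg_day = log.registration.normalize()
    cut = pd.Timestamp(window.cutoff, tz=log.registration.tz)
    c = (cut - reg_day).days
    if c < 0:
        raise InputError("registration after study cutoff")
    return int(c)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def successful_installation(log: UploadLog, params: RetentionParams = RetentionParams()) -> bool:
    """True iff at least one upload occurred strictly within
    ``install_window_days`` of registration."""
    if len(log.timestamps) == 0:
        return False
    limit = log.registration + pd.Timedelta(days=params.install_window_days)
    return bool(log.timestamps[0] < limit)


def churn_time(
    log: UploadLog,
    window: StudyWindow,
    params: RetentionParams = RetentionParams(),
) -> tuple[int, int]:
    """(duration_days, event) for one user/stream.

    Scans upload-day gaps in chronological order, including the final gap from
    the last upload to the cutoff. A gap qualifies when it contains at least
    ``gap_days`` whole days with no upload, all observed on or before the
    cutoff. The earliest qualifying gap defines churn (event=1) anchored at
    the last upload before it (or the first silent day under the
    ``gap_start`` anchor); re-entry after a qualifying silence is ignored.
    Otherwise the user is censored at the cutoff (event=0, duration =
    cutoff − registration in whole days).
    """
    if len(log.timestamps) == 0:
        raise InputError("churn_time requires a non-empty upload log")
    days = _day_offsets(log)
    c = _cutoff_day(log, window)
    days = days[days <= c]
    if len(days) == 0:
        raise InputError("no uploads on or before the study cutoff")
    return _churn_from_days(days, c, params)


def _churn_from_days(
    days: np.ndarray, cutoff_day: int, params: RetentionParams
) -> tuple[int, int]:
    """Gap scan on sorted unique whole-day upload offsets."""
    anchor_shift = 1 if params.churn_anchor == "gap_start" else 0
    gaps = np.diff(days) - 1  # silent days between consecutive upload days
    hit = np.nonzero(gaps >= params.gap_days)[0]
    if len(hit):
        return int(days[hit[0]]) + anchor_shift, 1
    if cutoff_day - int(days[-1]) >= params.gap_days:
        return int(days[-1]) + anchor_shift, 1
    return cutoff_day, 0


def apply_exclusions(
    users: pd.DataFrame,
    uploads: pd.DataFrame,
    params: RetentionParams = RetentionParams(),
) -> tuple[pd.DataFrame, dict]:
    """Apply the cohort inclusion rules.

    ``users``: one row per registered user with columns user_id,
    registration (tz-aware timestamp or date), platform, occupation, age,
    gender. ``uploads``: rows user_id, stream, timestamp.

    Users missing any demographic field are dropped first; of the remainder,
    users with no upload (any stream) within the installation window are
    dropped. Returns (included users, report dict with counts per reason).
    """
    demo_cols = ["platform", "occupation", "age", "gender"]
    for col in ["user_id", "registration", *demo_cols]:
        if col not in users.columns:
            raise InputError(f"users table missing column {col!r}")
    n_total = len(users)
    complete = users.dropna(subset=demo_cols)
    n_missing = n_total - len(complete)

    reg = _as_timestamps(complete["registration"])
    if len(uploads):
        upl = uploads[["user_id", "timestamp"]].copy()
        upl["timestamp"] = _as_timestamps(upl["timestamp"])
        first_upload = upl.groupby("user_id")["timestamp"].min().rename("first_upload")
    else:
        first_upload = pd.Series(
            dtype="datetime64[ns, UTC]", name="first_upload",
            index=pd.Index([], name="user_id"),
        )
    fu = (
        complete[["user_id"]]
        .merge(first_upload, left_on="user_id", right_index=True, how="left")
        ["first_upload"]
    )
    fu.index = complete.index
    limit = reg + pd.Timedelta(days=params.install_window_days)
    installed = fu.notna() & (fu < limit)
    included = complete[installed.to_numpy()].reset_index(drop=True)
    report = {
        "n_total": int(n_total),
        "n_missing_demographics": int(n_missing),
        "n_failed_installation": int(len(complete) - len(included)),
        "n_included": int(len(included)),
    }
    return included, report


def _as_timestamps(s: pd.Series) -> pd.Series:
    """Coerce a column to tz-aware timestamps (naive values get UTC)."""
    out = pd.to_datetime(s, format="ISO8601" if s.dtype == object else None)
    if getattr(out.dtype, "tz", None) is None and np.issubdtype(out.dtype, np.datetime64):
        out = out.dt.tz_localize("UTC")
    return out


def build_retention_table(
    users: pd.DataFrame,
    uploads: pd.DataFrame,
    window: StudyWindow,
    params: RetentionParams = RetentionParams(),
) -> pd.DataFrame:
    """One survival row per (user, stream), ordered by (user_id, stream).

    Streams are handled independently: a user with no uploads at all in one
    stream is anchored at the registration day (duration 0, event 1 if a full
    silent period fits before the cutoff, else censored).

    Columns: user_id, stream, duration_days, event, platform, occupation,
    age, gender.
    """
    rows = []
    users = users.reset_index(drop=True)
    reg = _as_timestamps(users["registration"])
    reg_day_by_uid = dict(
        zip(users["user_id"].astype(str), reg.dt.normalize().dt.tz_localize(None))
    )
    grouped: dict = {}
    if len(uploads):
        upl = uploads[["user_id", "stream", "timestamp"]].copy()
        upl["user_id"] = upl["user_id"].astype(str)
        upl["timestamp"] = _as_timestamps(upl["timestamp"])
        # local calendar day of each upload and of registration, tz dropped
        ts_day = upl["timestamp"].dt.normalize().dt.tz_localize(None).to_numpy()
        reg_norm = upl["user_id"].map(reg_day_by_uid).to_numpy(dtype="datetime64[ns]")
        upl["day"] = ((ts_day - reg_norm) / np.timedelta64(1, "D")).astype(np.int64)
        grouped = {
            k: np.unique(v["day"].to_numpy())
            for k, v in upl.groupby(["user_id", "stream"], sort=False)
        }
    for i, row in users.iterrows():
        uid = str(row["user_id"])
        r = reg.iloc[i]
        cutoff_day = int((pd.Timestamp(window.cutoff, tz=r.tz) - r.normalize()).days)
        if cutoff_day < 0:
            raise InputError(f"user {uid} registered after the study cutoff")
        for stream in STREAMS:
            days = grouped.get((uid, stream))
            if days is not None and len(days):
                days = days[days <= cutoff_day]
            if days is not None and len(days):
                if days[0] < 0:
                    raise InputError(f"user {uid} has uploads before registration")
                dur, ev = _churn_from_days(days, cutoff_day, params)
            else:
                # No uploads in this stream: the registration day anchors the
                # scan, so the first silent period starts on day 1.
                if cutoff_day >= params.gap_days:
                    dur, ev = (1 if params.churn_anchor == "gap_start" else 0), 1
                else:
                    dur, ev = cutoff_day, 0
            rows.append(
                {
                    "user_id": uid,
                    "stream": stream,
                    "duration_days": dur,
                    "event": ev,
                    "platform": row["platform"],
                    "occupation": row["occupation"],
                    "age": row.get("age", np.nan),
                    "gender": row.get("gender", ""),
                }
            )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(["user_id", "stream"], kind="stable").reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_users_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str})
    if "registration_date" in df.columns:
        df = df.rename(columns={"registration_date": "registration"})
    return df


def read_uploads_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"user_id": str, "stream": str})
    missing = {"user_id", "stream", "timestamp"} - set(df.columns)
    if missing:
        raise InputError(f"upload CSV missing columns: {sorted(missing)}")
    bad = set(df["stream"].unique()) - set(STREAMS)
    if bad:
        raise InputError(f"unknown streams in upload CSV: {sorted(bad)}")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    return df
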