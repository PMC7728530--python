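"""Synthetic cohort generator with known ground-truth churn.

The study data behind the retention analysis (GPS fixes and upload logs of a
work-hours app deployed to Taiwanese hospital staff) are not public, so every
downstream stage is exercised on simulated cohorts whose churn process is
known exactly:

* covariates — platform (Android/iOS), occupation (five categories), age,
  gender — drawn at the deployment's reported margins;
* per-user, per-stream churn times drawn from a piecewise-exponential hazard
  on the day intervals [0,7), [7,28), [28,inf), with per-(stream, platform)
  rates and an optional multiplicative occupation effect;
* upload logs: daily passive uploads while the user is retained; active
  uploads either daily ("persistence" mode, the calibration default) or on
  first-of-month survey dates;
* optional commuter GPS traces (home/work geometry, 10-minute sampling,
  Gaussian position noise, dropout) for the geofence stage.

The default hazards are calibrated in closed form from the deployment's
published one-week / one-month retention readouts via
:func:`calibrate_hazards`, so the generator's defaults reproduce those
survival rates in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .geofence import DEFAULT_TZ, GeoPoint
from .retention import STREAMS, StudyWindow, RetentionParams, build_retention_table
from .survival import kaplan_meier, survival_at

#: One-week / one-month retention readouts used to calibrate default hazards,
#: overall per stream and by (stream, platform).
CALIBRATION_ANCHORS = {
    ("passive", None): (0.467, 0.273),
    ("active", None): (0.222, 0.034),
    ("passive", "Android"): (0.692, 0.495),
    ("passive", "iOS"): (0.362, 0.167),
    ("active", "Android"): (0.083, 0.008),
    ("active", "iOS"): (0.286, 0.045),
}

#: Android share consistent with the anchors: the unique mixing weight that
#: reconciles the overall rates with the per-platform rates at both horizons
#: (e.g. (46.7-36.2)/(69.2-36.2) = 0.318; the one-month and active-stream
#: readouts give the same value to within rounding).
DEFAULT_ANDROID_SHARE = 0.32

DEFAULT_OCCUPATION_MIX = {
    "resident_physician": 128 / 342,
    "visiting_staff": 60 / 342,
    "medical_student": 40 / 342,
    "nurse": 58 / 342,
    "other": 56 / 342,
}

NEVER = 10_000  # churn day standing in for "never churns" (beyond any window)


# ---------------------------------------------------------------------------
# Piecewise-exponential churn model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PiecewiseExponential:
    """Daily hazard rates on [0, b1), [b1, b2), [b2, inf) with breaks in days."""

    rates: tuple[float, float, float]
    breaks: tuple[float, float] = (7.0, 28.0)

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates):
            raise ConfigurationError("hazard rates must be >= 0")
        if not 0 < self.breaks[0] < self.breaks[1]:
            raise ConfigurationError("breaks must be increasing and positive")

    def scaled(self, factor: float) -> "PiecewiseExponential":
        """Proportional-hazards scaling (multiply every rate)."""
        if factor < 0:
            raise ConfigurationError("hazard factor must be >= 0")
        return PiecewiseExponential(
            tuple(r * factor for r in self.rates), self.breaks
        )

    def cumulative_hazard(self, t: float) -> float:
        l1, l2, l3 = self.rates
        b1, b2 = self.breaks
        if t <= b1:
            return l1 * t
        if t <= b2:
            return l1 * b1 + l2 * (t - b1)
        return l1 * b1 + l2 * (b2 - b1) + l3 * (t - b2)

    def survival(self, t: float) -> float:
        return math.exp(-self.cumulative_hazard(t))

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Continuous churn times by inverting the cumulative hazard."""
        l1, l2, l3 = self.rates
        b1, b2 = self.breaks
        target = rng.exponential(size=size)  # -log U
        h1 = l1 * b1
        h2 = h1 + l2 * (b2 - b1)
        out = np.full(size, float(NEVER))
        with np.errstate(divide="ignore", invalid="ignore"):
            seg1 = target < h1
            if l1 > 0:
                out[seg1] = target[seg1] / l1
            seg2 = (~seg1) & (target < h2)
            if l2 > 0:
                out[seg2] = b1 + (target[seg2] - h1) / l2
            seg3 = (~seg1) & (~seg2)
            if l3 > 0:
                out[seg3] = np.minimum(b2 + (target[seg3] - h2) / l3, NEVER)
        return out


def calibrate_hazards(
    s_week: float,
    s_month: float,
    t_week: float = 7.0,
    t_month: float = 28.0,
) -> tuple[float, float]:
    """Closed-form daily hazards reproducing two survival readouts.

    With S(t_week) = s_week and S(t_month) = s_month under a two-piece
    exponential model, lambda1 = -ln(s_week)/t_week on [0, t_week) and
    lambda2 = -ln(s_month/s_week)/(t_month - t_week) on [t_week, t_month);
    plugging back recovers both readouts exactly.
    """
    if not (0.0 < s_month <= s_week <= 1.0):
        raise InputError("require 0 < s_month <= s_week <= 1")
    lam1 = -math.log(s_week) / t_week
    lam2 = -math.log(s_month / s_week) / (t_month - t_week)
    return lam1, lam2


def hazard_from_anchors(
    s_week: float, s_month: float, breaks: tuple[float, float] = (7.0, 28.0)
) -> PiecewiseExponential:
    """Piecewise-exponential model from week/month readouts; the post-month
    hazard continues at the [7, 28) rate."""
    lam1, lam2 = calibrate_hazards(s_week, s_month, breaks[0], breaks[1])
    return PiecewiseExponential((lam1, lam2, lam2), breaks)


def default_hazards() -> dict[tuple[str, str], PiecewiseExponential]:
    """Per-(stream, platform) models calibrated from the published readouts."""
    return {
        (stream, platform): hazard_from_anchors(*CALIBRATION_ANCHORS[(stream, platform)])
        for stream in STREAMS
        for platform in ("Android", "iOS")
    }


def uniform_hazards(
    anchors: Mapping[str, tuple[float, float]] | None = None,
) -> dict[tuple[str, str], PiecewiseExponential]:
    """Stream-level models (identical across platforms), by default from the
    overall week/month readouts."""
    if anchors is None:
        anchors = {s: CALIBRATION_ANCHORS[(s, None)] for s in STREAMS}
    out = {}
    for stream, (sw, sm) in anchors.items():
        h = hazard_from_anchors(sw, sm)
        for platform in ("Android", "iOS"):
            out[(stream, platform)] = h
    return out


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraceGeometry:
    """Commuter-trace geometry: workplace anchor, home distance range (km),
    10-minute sampling between daily start/end hours, Gaussian position noise
    (meters) and independent fix dropout."""

    workplace: GeoPoint = GeoPoint(25.04, 121.52)
    home_distance_km: tuple[float, float] = (4.0, 12.0)
    fix_interval_min: float = 10.0
    day_start_hour: float = 6.0
    day_end_hour: float = 22.0
    commute_min: float = 30.0
    noise_sd_m: float = 30.0
    dropout: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ConfigurationError("dropout must be in [0, 1]")
        if self.fix_interval_min <= 0 or self.noise_sd_m < 0:
            raise ConfigurationError("invalid trace geometry")


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Defaults are the study conditions of the deployment being emulated:
    342 users, Android share 0.32, occupation margins around the reported
    medical-staff structure, age 33.76 (SD 7.01) truncated to [20, 59],
    registrations over Aug 2018 - Jan 2019 with observation cutoff
    2019-03-31, and per-(stream, platform) hazards calibrated from the
    published week/month retention readouts.
    """

    n_users: int = 342
    android_share: float = DEFAULT_ANDROID_SHARE
    occupation_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OCCUPATION_MIX)
    )
    male_share: float = 224 / 342
    age_mean: float = 33.76
    age_sd: float = 7.01
    age_range: tuple[float, float] = (20.0, 59.0)
    registration_start: date = date(2018, 8, 1)
    registration_end: date = date(2019, 1, 31)
    cutoff: date = date(2019, 3, 31)
    hazards: Mapping[tuple[str, str], PiecewiseExponential] = field(
        default_factory=default_hazards
    )
    #: multiplicative occupation effect on the hazard, per stream
    #: (e.g. {"active": {"resident_physician": 0.119}}); missing keys mean 1.
    occupation_hr: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    active_cadence: str = "daily"  # "daily" (persistence) or "monthly" (survey)
    tz: str = DEFAULT_TZ
    seed: int = 20180801
    trace: TraceGeometry = field(default_factory=TraceGeometry)

    def __post_init__(self) -> None:
        if self.n_users <= 0:
            raise ConfigurationError("n_users must be positive")
        if not 0.0 <= self.android_share <= 1.0:
            raise ConfigurationError("android_share must be in [0, 1]")
        tot = sum(self.occupation_mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise ConfigurationError("occupation_mix must sum to 1")
        if any(v < 0 for v in self.occupation_mix.values()):
            raise ConfigurationError("occupation_mix proportions must be >= 0")
        if self.registration_start > self.registration_end:
            raise ConfigurationError("registration window inverted")
        if self.registration_end >= self.cutoff:
            raise ConfigurationError("registrations must end before the cutoff")
        if self.active_cadence not in ("daily", "monthly"):
            raise ConfigurationError("active_cadence must be 'daily' or 'monthly'")
        for key in self.hazards:
            if key[0] not in STREAMS or key[1] not in ("Android", "iOS"):
                raise ConfigurationError(f"unknown hazard key {key}")

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(self.registration_start, self.cutoff)


@dataclass(frozen=True)
class SyntheticCohort:
    """users: per-user covariates and registration; uploads: (user_id,
    stream, timestamp) rows; ground_truth: true last-upload churn day per
    (user, stream), NEVER when the user outlives any window; workplaces and
    traces are present when trace generation was requested."""

    users: pd.DataFrame
    uploads: pd.DataFrame
    ground_truth: pd.DataFrame
    workplaces: pd.DataFrame | None = None
    traces: pd.DataFrame | None = None
    config: CohortConfig | None = None


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: CohortConfig,
    include_traces: bool = False,
    trace_days: int = 5,
    trace_users: int | None = None,
) -> SyntheticCohort:
    """Draw a cohort under the configured churn model; reproducible under
    ``config.seed``.

    Churn is simulated in continuous time from the piecewise-exponential
    hazard; the last upload day is the ceiling of the continuous churn time,
    so that P(last day > d) equals the model survival S(d) at whole days d.
    Uploads stop permanently at the churn day or the user's cutoff,
    whichever is earlier.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    user_ids = np.array([f"u{i:05d}" for i in range(n)])
    platform = np.where(rng.random(n) < config.android_share, "Android", "iOS")
    occs = list(config.occupation_mix)
    occupation = rng.choice(occs, size=n, p=[config.occupation_mix[o] for o in occs])
    gender = np.where(rng.random(n) < config.male_share, "M", "F")
    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, size=n), *config.age_range
    ).round(1)
    span = (config.registration_end - config.registration_start).days + 1
    reg_offset = rng.integers(0, span, size=n)
    reg_dates = np.array(
        [config.registration_start + timedelta(days=int(d)) for d in reg_offset]
    )
    followup = np.array([(config.cutoff - d).days for d in reg_dates])

    users = pd.DataFrame(
        {
            "user_id": user_ids,
            "registration": pd.Series(
                pd.to_datetime(list(reg_dates))
            ).dt.tz_localize(config.tz),
            "platform": platform,
            "occupation": occupation,
            "age": age,
            "gender": gender,
        }
    )

    upload_rows = {"user_id": [], "stream": [], "day": []}
    gt_rows = {"user_id": [], "stream": [], "true_churn_day": []}
    for stream in STREAMS:
        churn_day = np.empty(n, dtype=int)
        for plat in ("Android", "iOS"):
            mask = platform == plat
            if not mask.any():
                continue
            base = config.hazards.get((stream, plat))
            if base is None:
                raise ConfigurationError(f"no hazard configured for {(stream, plat)}")
            idx = np.nonzero(mask)[0]
            # draw per occupation group so multiplicative effects apply
            t_cont = np.empty(idx.size)
            occ_here = occupation[idx]
            for occ in np.unique(occ_here):
                factor = config.occupation_hr.get(stream, {}).get(occ, 1.0)
                sub = occ_here == occ
                t_cont[sub] = base.scaled(factor).sample(rng, int(sub.sum()))
            churn_day[idx] = np.minimum(np.ceil(t_cont), NEVER).astype(int)
        for i in range(n):
            last = min(churn_day[i], followup[i])
            if stream == "active" and config.active_cadence == "monthly":
                days = _monthly_days(reg_dates[i], last)
            else:
                days = np.arange(0, last + 1)
            upload_rows["user_id"].append(np.repeat(user_ids[i], days.size))
            upload_rows["stream"].append(np.repeat(stream, days.size))
            upload_rows["day"].append(days)
            gt_rows["user_id"].append(user_ids[i])
            gt_rows["stream"].append(stream)
            gt_rows["true_churn_day"].append(int(churn_day[i]))

    day = np.concatenate(upload_rows["day"])
    uid = np.concatenate(upload_rows["user_id"])
    stream_col = np.concatenate(upload_rows["stream"])
    reg_by_uid = dict(zip(user_ids, reg_dates))
    base_day = np.array([reg_by_uid[u] for u in uid], dtype="datetime64[D]")
    ts_naive = base_day.astype("datetime64[m]") + (day * 1440 + 12 * 60).astype(
        "timedelta64[m]"
    )
    if day.size:
        ts = pd.Series(ts_naive.astype("datetime64[ns]")).dt.tz_localize(config.tz)
    else:
        ts = pd.Series([], dtype=f"datetime64[ns, {config.tz}]")
    uploads = pd.DataFrame({"user_id": uid, "stream": stream_col, "timestamp": ts})
    ground_truth = pd.DataFrame(gt_rows)

    workplaces = traces = None
    if include_traces:
        n_trace = n if trace_users is None else min(trace_users, n)
        workplaces, traces = _generate_traces(
            config, rng, users.iloc[:n_trace], reg_dates[:n_trace], trace_days
        )
    return SyntheticCohort(users, uploads, ground_truth, workplaces, traces, config)


def _monthly_days(reg: date, last_day: int) -> np.ndarray:
    """Day offsets of first-of-month dates in [reg, reg + last_day]."""
    days = []
    d = reg
    end = reg + timedelta(days=int(last_day))
    while d <= end:
        if d.day == 1:
            days.append((d - reg).days)
        d += timedelta(days=1)
    return np.asarray(days, dtype=int)


# ---------------------------------------------------------------------------
# GPS trace generation
# ---------------------------------------------------------------------------

def _offset_point(origin: GeoPoint, dx_km: float, dy_km: float) -> GeoPoint:
    lat = origin.lat + dy_km / 111.19492664455873
    lon = origin.lon + dx_km / (111.19492664455873 * math.cos(math.radians(origin.lat)))
    return GeoPoint(lat, lon)


def generate_trace(
    user_id: str,
    start_day: date,
    n_days: int,
    schedule: list[tuple[float, float] | None],
    geometry: TraceGeometry,
    home: GeoPoint,
    rng: np.random.Generator,
    tz: str = DEFAULT_TZ,
) -> pd.DataFrame:
    """Simulate one user's fixes over ``n_days`` days.

    ``schedule[k]`` gives (arrive_hour, depart_hour) of workplace presence on
    day k, or None for a day off. The user sits at home outside work, at the
    workplace during [arrive, depart], and moves linearly between them over
    ``commute_min`` minutes ending at arrival / starting at departure.
    Gaussian noise (``noise_sd_m``) and Bernoulli dropout are applied per fix.
    """
    if len(schedule) != n_days:
        raise InputError("schedule length must equal n_days")
    step = geometry.fix_interval_min
    per_day = np.arange(
        geometry.day_start_hour * 60.0, geometry.day_end_hour * 60.0 + 1e-9, step
    )
    rows = {"user_id": [], "timestamp": [], "lat": [], "lon": []}
    work = geometry.workplace
    for k in range(n_days):
        sched = schedule[k]
        day0 = pd.Timestamp(start_day + timedelta(days=k), tz=tz)
        for m in per_day:
            hour = m / 60.0
            lat, lon = home.lat, home.lon
            if sched is not None:
                arrive, depart = sched
                c = geometry.commute_min / 60.0
                if arrive <= hour <= depart:
                    lat, lon = work.lat, work.lon
                elif arrive - c <= hour < arrive:
                    f = (hour - (arrive - c)) / c
                    lat = home.lat + f * (work.lat - home.lat)
                    lon = home.lon + f * (work.lon - home.lon)
                elif depart < hour <= depart + c:
                    f = (hour - depart) / c
                    lat = work.lat + f * (home.lat - work.lat)
                    lon = work.lon + f * (home.lon - work.lon)
            if rng.random() < geometry.dropout:
                continue
            if geometry.noise_sd_m > 0:
                noisy = _offset_point(
                    GeoPoint(lat, lon),
                    rng.normal(0, geometry.noise_sd_m / 1000.0),
                    rng.normal(0, geometry.noise_sd_m / 1000.0),
                )
                lat, lon = noisy.lat, noisy.lon
            rows["user_id"].append(user_id)
            rows["timestamp"].append((day0 + pd.Timedelta(minutes=m)).isoformat())
            rows["lat"].append(lat)
            rows["lon"].append(lon)
    return pd.DataFrame(rows)


def _generate_traces(config, rng, users, reg_dates, trace_days):
    geom = config.trace
    wp_rows = {"user_id": [], "workplace_id": [], "lat": [], "lon": []}
    frames = []
    for i, row in enumerate(users.itertuples()):
        theta = rng.uniform(0, 2 * math.pi)
        dist = rng.uniform(*geom.home_distance_km)
        home = _offset_point(
            geom.workplace, dist * math.cos(theta), dist * math.sin(theta)
        )
        wp_rows["user_id"].append(row.user_id)
        wp_rows["workplace_id"].append("w0")
        wp_rows["lat"].append(geom.workplace.lat)
        wp_rows["lon"].append(geom.workplace.lon)
        schedule = []
        for k in range(trace_days):
            d = reg_dates[i] + timedelta(days=k)
            if d.weekday() >= 5:
                schedule.append(None)
            else:
                arrive = 8.0 + rng.uniform(0, 1.5)
                depart = 17.0 + rng.uniform(0, 2.0)
                schedule.append((arrive, depart))
        frames.append(
            generate_trace(
                row.user_id, reg_dates[i], trace_days, schedule, geom, home, rng,
                tz=config.tz,
            )
        )
    workplaces = pd.DataFrame(wp_rows)
    traces = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["user_id", "timestamp", "lat", "lon"]
    )
    return workplaces, traces


# ---------------------------------------------------------------------------
# Calibration utilities
# ---------------------------------------------------------------------------

def km_readouts(
    cohort: SyntheticCohort,
    days=(7, 28),
    params: RetentionParams = RetentionParams(),
) -> pd.DataFrame:
    """Run the retention pipeline on a cohort and read KM survival at the
    given days, overall per stream and per stream x platform."""
    cfg = cohort.config
    window = cfg.window if cfg is not None else None
    if window is None:
        raise InputError("cohort carries no config/window")
    table = build_retention_table(cohort.users, cohort.uploads, window, params)
    rows = []
    for stream in STREAMS:
        sub = table[table["stream"] == stream]
        strata = [("all", sub)] + [
            (plat, sub[sub["platform"] == plat]) for plat in ("Android", "iOS")
        ]
        for name, s in strata:
            if len(s) == 0:
                continue
            curve = kaplan_meier(
                s["duration_days"].to_numpy(float), s["event"].to_numpy(int)
            )
            row = {"stream": stream, "platform": name, "n": len(s)}
            for d in days:
                row[f"S{d}"] = survival_at(curve, d)
            rows.append(row)
    return pd.DataFrame(rows)


def run_km_replicates(
    config: CohortConfig,
    n_replicates: int,
    base_seed: int = 1,
    days=(7, 28),
) -> pd.DataFrame:
    """Generate ``n_replicates`` cohorts (seeds base_seed .. base_seed +
    n_replicates - 1) and stack their KM readouts."""
    frames = []
    for r in range(n_replicates):
        cfg = replace(config, seed=int(base_seed + r))
        out = km_readouts(generate_cohort(cfg), days=days)
        out.insert(0, "replicate", r)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def simulate_ph_cohort(
    n: int,
    rng: np.random.Generator,
    baseline_rate: float,
    hr_ios: float = 1.0,
    hr_resident: float = 1.0,
    android_share: float = DEFAULT_ANDROID_SHARE,
    resident_share: float = 128 / 342,
    followup_range: tuple[float, float] = (59.0, 242.0),
):
    """Continuous-time proportional-hazards churn for recovery studies.

    Durations are exponential with rate baseline * hr_ios^iOS *
    hr_resident^resident, administratively censored at a uniform follow-up.
    Returns (durations, events, X, names) with X columns (iOS, resident).
    """
    if baseline_rate <= 0:
        raise InputError("baseline_rate must be positive")
    ios = (rng.random(n) >= android_share).astype(float)
    resident = (rng.random(n) < resident_share).astype(float)
    rate = baseline_rate * hr_ios**ios * hr_resident**resident
    t = rng.exponential(1.0 / rate)
    f = rng.uniform(*followup_range, size=n)
    events = (t <= f).astype(int)
    durations = np.minimum(t, f)
    X = np.column_stack([ios, resident])
    return durations, events, X, ("platform_iOS", "resident_physician")
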