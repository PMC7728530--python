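"""Run configuration, stage orchestration and report generation.

Every stage reads and writes plain CSV so intermediates stay independently
inspectable; figures and the markdown report are derived artifacts, never
inputs. A run is configured by a JSON document validated against the
pydantic :class:`RunConfig` model (``dwellsurv schema`` prints the JSON
schema), providing either input CSV paths or a simulation block — exactly
one of the two.
"""

from __future__ import annotations

import json
import logging
from datetime import date
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import cohort as cohort_mod
from . import geofence, retention, survival
from .errors import ConfigurationError, InputError

log = logging.getLogger("dwellsurv")


# ---------------------------------------------------------------------------
# Configuration model
# ---------------------------------------------------------------------------

class GeofenceSettings(BaseModel):
    radius_km: float = 1.0
    sample_interval_min: float = 10.0
    confirm_min: float = 30.0

    def to_params(self) -> geofence.GeofenceParams:
        return geofence.GeofenceParams(
            self.radius_km, self.sample_interval_min, self.confirm_min
        )


class RetentionSettings(BaseModel):
    gap_days: int = 28
    install_window_days: int = 28
    churn_anchor: str = "last_upload"

    def to_params(self) -> retention.RetentionParams:
        return retention.RetentionParams(
            self.gap_days, self.install_window_days, self.churn_anchor  # type: ignore[arg-type]
        )


class WindowSettings(BaseModel):
    start: date = date(2018, 8, 1)
    cutoff: date = date(2019, 3, 31)

    def to_window(self) -> retention.StudyWindow:
        return retention.StudyWindow(self.start, self.cutoff)


class InputPaths(BaseModel):
    users: str
    uploads: str
    traces: Optional[str] = None
    workplaces: Optional[str] = None


class SimulateSettings(BaseModel):
    n_users: int = 342
    android_share: float = cohort_mod.DEFAULT_ANDROID_SHARE
    active_cadence: str = "daily"
    include_traces: bool = False
    trace_days: int = 5
    trace_users: int = 10
    registration_start: date = date(2018, 8, 1)
    registration_end: date = date(2019, 1, 31)
    cutoff: date = date(2019, 3, 31)

    def to_config(self, seed: int) -> cohort_mod.CohortConfig:
        return cohort_mod.CohortConfig(
            n_users=self.n_users,
            android_share=self.android_share,
            active_cadence=self.active_cadence,
            registration_start=self.registration_start,
            registration_end=self.registration_end,
            cutoff=self.cutoff,
            seed=seed,
        )


class RunConfig(BaseModel):
    """Top-level run configuration; provide exactly one of ``inputs`` /
    ``simulate``."""

    inputs: Optional[InputPaths] = None
    simulate: Optional[SimulateSettings] = None
    geofence: GeofenceSettings = Field(default_factory=GeofenceSettings)
    retention: RetentionSettings = Field(default_factory=RetentionSettings)
    window: WindowSettings = Field(default_factory=WindowSettings)
    out: str = "out"
    seed: int = 20180801
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _exactly_one_source(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("provide exactly one of 'inputs' or 'simulate'")
        return self


def load_config(path) -> RunConfig:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"malformed config JSON: {exc}") from exc
    try:
        return RunConfig.model_validate(payload)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(f"invalid run config: {exc}") from exc


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _outdir(config: RunConfig) -> Path:
    p = Path(config.out)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(config: RunConfig) -> dict[str, Path]:
    if config.simulate is None:
        raise ConfigurationError("simulate stage needs a 'simulate' block")
    cc = config.simulate.to_config(seed=config.seed)
    cohort = cohort_mod.generate_cohort(
        cc,
        include_traces=config.simulate.include_traces,
        trace_days=config.simulate.trace_days,
        trace_users=config.simulate.trace_users,
    )
    out = _outdir(config)
    paths = {}
    users = cohort.users.copy()
    users["registration"] = users["registration"].map(lambda x: x.isoformat())
    users = users.rename(columns={"registration": "registration_date"})
    paths["users"] = out / "users.csv"
    users.to_csv(paths["users"], index=False)
    uploads = cohort.uploads.copy()
    uploads["timestamp"] = uploads["timestamp"].map(lambda x: x.isoformat())
    paths["uploads"] = out / "uploads.csv"
    uploads.to_csv(paths["uploads"], index=False)
    paths["ground_truth"] = out / "ground_truth.csv"
    cohort.ground_truth.to_csv(paths["ground_truth"], index=False)
    if cohort.workplaces is not None:
        paths["workplaces"] = out / "workplaces.csv"
        cohort.workplaces.to_csv(paths["workplaces"], index=False)
    if cohort.traces is not None:
        paths["traces"] = out / "traces.csv"
        cohort.traces.to_csv(paths["traces"], index=False)
    log.info("simulated cohort of %d users -> %s", cc.n_users, out)
    return paths


def _require(path: Path, stage: str) -> Path:
    if not Path(path).exists():
        raise InputError(
            f"{stage}: missing upstream file {path}; run the producing stage first"
        )
    return Path(path)


def _resolve_input(config: RunConfig, key: str, default_name: str) -> Path:
    if config.inputs is not None:
        val = getattr(config.inputs, key, None)
        if val:
            return Path(val)
    return Path(config.out) / default_name


def stage_workhours(config: RunConfig) -> dict[str, Path]:
    trace_path = _require(_resolve_input(config, "traces", "traces.csv"), "workhours")
    wp_path = _require(
        _resolve_input(config, "workplaces", "workplaces.csv"), "workhours"
    )
    trace = geofence.read_trace_csv(trace_path)
    workplaces = geofence.read_workplaces_csv(wp_path)
    params = config.geofence.to_params()
    sessions = geofence.sessions_from_frames(trace, workplaces, params)
    out = _outdir(config)
    sess_path = out / "sessions.csv"
    geofence.sessions_to_frame(sessions).to_csv(sess_path, index=False)
    by_user: dict[str, list[geofence.WorkSession]] = {}
    for s in sessions:
        by_user.setdefault(s.user_id, []).append(s)
    daily = []
    for uid in sorted(by_user):
        daily.extend(geofence.daily_records(by_user[uid]))
    daily_path = out / "daily_hours.csv"
    geofence.daily_to_frame(daily).to_csv(daily_path, index=False)
    log.info("detected %d sessions for %d users", len(sessions), len(by_user))
    return {"sessions": sess_path, "daily": daily_path}


def stage_retention(config: RunConfig) -> dict[str, Path]:
    users_path = _require(_resolve_input(config, "users", "users.csv"), "retention")
    uploads_path = _require(
        _resolve_input(config, "uploads", "uploads.csv"), "retention"
    )
    users = retention.read_users_csv(users_path)
    uploads = retention.read_uploads_csv(uploads_path)
    params = config.retention.to_params()
    included, report = retention.apply_exclusions(users, uploads, params)
    table = retention.build_retention_table(
        included, uploads, config.window.to_window(), params
    )
    out = _outdir(config)
    table_path = out / "retention.csv"
    table.to_csv(table_path, index=False)
    report_path = out / "exclusions.json"
    report_path.write_text(json.dumps(report, indent=2))
    log.info("retention table: %d records (%s)", len(table), report)
    return {"retention": table_path, "exclusions": report_path}


def stage_survive(config: RunConfig, univariable: bool = False) -> dict[str, Path]:
    table_path = _require(Path(config.out) / "retention.csv", "survive")
    table = pd.read_csv(table_path, dtype={"user_id": str})
    if len(table) == 0:
        raise InputError("no records in retention table")
    results = survival.fit_study_models(table, univariable=univariable)
    out = _outdir(config)
    paths = {}
    for key, curve in results.km.items():
        name = key if isinstance(key, str) else "_".join(key)
        p = out / f"km_{name}.csv"
        curve.to_frame().to_csv(p, index=False)
        paths[f"km_{name}"] = p
    cox_payload = {}
    for stream, fit in results.cox.items():
        fits = fit if isinstance(fit, dict) else {"joint": fit}
        cox_payload[stream] = {
            label: {
                "covariates": list(f.names),
                "coef": f.coef.tolist(),
                "se": f.se.tolist(),
                "hazard_ratio": f.hazard_ratios.tolist(),
                "ci95_lower": f.ci_lower.tolist(),
                "ci95_upper": f.ci_upper.tolist(),
                "p_value": f.p_values.tolist(),
                "ties_method": f.ties_method,
                "converged": f.converged,
                "n_iterations": f.n_iterations,
                "n": f.n,
                "n_events": f.n_events,
            }
            for label, f in fits.items()
        }
    cox_path = out / "cox.json"
    cox_path.write_text(json.dumps(cox_payload, indent=2))
    paths["cox"] = cox_path
    lr_payload = {
        name: {
            "chi_square": r.chi_square,
            "df": r.df,
            "p_value": r.p_value,
            "observed": r.observed.tolist(),
            "expected": r.expected.tolist(),
        }
        for name, r in results.logrank.items()
    }
    lr_path = out / "logrank.json"
    lr_path.write_text(json.dumps(lr_payload, indent=2))
    paths["logrank"] = lr_path
    paths.update(_plot_curves(results, out))
    return paths


def _plot_curves(results: survival.StudyResults, out: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    paths = {}

    def steps(ax, curve, label):
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=label)

    specs = [
        ("streams", [("passive", "passive"), ("active", "active")],
         "User retention by data stream"),
        ("passive_platforms",
         [(("passive", "Android"), "Android"), (("passive", "iOS"), "iOS")],
         "Passive-data retention by platform"),
        ("active_platforms",
         [(("active", "Android"), "Android"), (("active", "iOS"), "iOS")],
         "Active-data retention by platform"),
    ]
    for name, series, title in specs:
        keys = [k for k, _ in series if k in results.km]
        if not keys:
            continue
        fig, ax = plt.subplots(figsize=(6, 4))
        for key, label in series:
            if key in results.km:
                steps(ax, results.km[key], label)
        ax.set_xlabel("days since registration")
        ax.set_ylabel("retention survival S(t)")
        ax.set_ylim(0, 1.02)
        ax.set_title(title)
        ax.legend()
        p = figdir / f"{name}.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[f"fig_{name}"] = p
    return paths


def stage_report(config: RunConfig) -> Path:
    out = _outdir(config)
    cox_path = _require(out / "cox.json", "report")
    lr_path = _require(out / "logrank.json", "report")
    cox = json.loads(cox_path.read_text())
    lr = json.loads(lr_path.read_text())
    lines = ["# Retention analysis report", ""]
    excl = out / "exclusions.json"
    if excl.exists():
        rep = json.loads(excl.read_text())
        lines += [
            "## Cohort",
            "",
            f"- registered users: {rep['n_total']}",
            f"- excluded, missing demographics: {rep['n_missing_demographics']}",
            f"- excluded, failed installation: {rep['n_failed_installation']}",
            f"- included: {rep['n_included']}",
            "",
        ]
    lines += ["## Kaplan-Meier survival", ""]
    for name in ("streams", "passive_platforms", "active_platforms"):
        p = out / "figures" / f"{name}.png"
        if p.exists():
            lines.append(f"![{name}](figures/{name}.png)")
    lines += ["", "## Log-rank tests", ""]
    lines.append("| comparison | chi-square | p |")
    lines.append("|---|---|---|")
    for name, r in lr.items():
        lines.append(f"| {name} | {r['chi_square']:.3f} | {r['p_value']:.3g} |")
    lines += ["", "## Cox proportional hazards", ""]
    lines.append("| stream | model | covariate | HR (95% CI) | p |")
    lines.append("|---|---|---|---|---|")
    for stream, fits in cox.items():
        for label, f in fits.items():
            for i, cov in enumerate(f["covariates"]):
                hr = f["hazard_ratio"][i]
                lo, hi = f["ci95_lower"][i], f["ci95_upper"][i]
                lines.append(
                    f"| {stream} | {label} | {cov} | "
                    f"{hr:.3f} ({lo:.3f}-{hi:.3f}) | {f['p_value'][i]:.3g} |"
                )
    report_path = out / "report.md"
    report_path.write_text("\n".join(lines) + "\n")
    return report_path
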