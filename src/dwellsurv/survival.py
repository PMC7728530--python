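"""Survival statistics from first principles.

Implements the three estimators the retention analysis rests on, without
delegating to a survival package:

* Kaplan-Meier product-limit estimator with Greenwood variance,
* two-sample log-rank test (hypergeometric variance, chi-square df=1),
* Cox proportional-hazards regression by Newton-Raphson on the log partial
  likelihood, with Efron (default) or Breslow handling of tied event times,
  Wald standard errors from the inverse observed information, and the score
  test at beta = 0.

All functions accept plain arrays (durations, event indicators, covariates);
thin wrappers consume the retention-table DataFrame produced by
:mod:`dwellsurv.retention`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConvergenceError, DegenerateInputError, InputError

TiesMethod = Literal["efron", "breslow"]


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate over the distinct event times of one group.

    ``survival[i]`` is S(event_times[i]); the curve is right-continuous and
    equal to 1 before the first event. ``greenwood_var`` is Greenwood's
    estimate of Var[S(t_i)].
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n: int

    def survival_at(self, t):
        return survival_at(self, t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "greenwood_se": np.sqrt(self.greenwood_var),
            }
        )


def kaplan_meier(durations, events) -> SurvivalCurve:
    """Kaplan-Meier estimator from right-censored durations.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i with
    d_i events and n_i subjects at risk; censored durations leave the curve
    unchanged and only shrink later risk sets.
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise InputError("kaplan_meier requires at least one record")
    if t.shape != e.shape:
        raise InputError("durations and events must have the same length")
    if np.any(t < 0):
        raise InputError("durations must be non-negative")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    n = t.size

    event_times = np.unique(t[e == 1])
    if event_times.size == 0:
        return SurvivalCurve(
            event_times=np.empty(0),
            at_risk=np.empty(0, dtype=int),
            events=np.empty(0, dtype=int),
            survival=np.empty(0),
            greenwood_var=np.empty(0),
            n=n,
        )
    # at risk at time s: subjects with duration >= s
    at_risk = n - np.searchsorted(t, event_times, side="left")
    d = np.array([int(np.sum((t == s) & (e == 1))) for s in event_times])
    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf)
        gw = surv**2 * np.cumsum(terms)
    gw = np.where(surv == 0.0, 0.0, gw)
    return SurvivalCurve(
        event_times=event_times,
        at_risk=at_risk.astype(int),
        events=d,
        survival=surv,
        greenwood_var=gw,
        n=n,
    )


def survival_at(curve: SurvivalCurve, t):
    """Right-continuous step-function evaluation of S at time(s) t >= 0."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise InputError("survival_at requires t >= 0")
    idx = np.searchsorted(curve.event_times, tt, side="right")
    s = np.concatenate([[1.0], curve.survival])
    out = s[idx]
    return float(out) if np.isscalar(t) or tt.ndim == 0 else out


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    observed: np.ndarray  # events per group (A, B)
    expected: np.ndarray  # expected events per group under H0


def log_rank(durations_a, events_a, durations_b, events_b) -> LogRankResult:
    """Two-sample log-rank test.

    Sums, over the pooled distinct event times, the group-A observed minus
    expected event counts with the hypergeometric variance of the 2x2 table
    at each time; the statistic (O-E)^2/V is chi-square with 1 df under the
    null of equal hazards.
    """
    ta = np.asarray(durations_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(durations_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise InputError("both groups must be non-empty")
    pooled_t = np.concatenate([ta, tb])
    pooled_e = np.concatenate([ea, eb])
    if pooled_e.sum() == 0:
        raise DegenerateInputError("log-rank undefined with no events at all")
    times = np.unique(pooled_t[pooled_e == 1])

    ta_s = np.sort(ta)
    tb_s = np.sort(tb)
    o_minus_e = 0.0
    var = 0.0
    obs = np.zeros(2)
    exp = np.zeros(2)
    for s in times:
        n1 = ta.size - np.searchsorted(ta_s, s, side="left")
        n2 = tb.size - np.searchsorted(tb_s, s, side="left")
        ntot = n1 + n2
        d1 = int(np.sum((ta == s) & (ea == 1)))
        d2 = int(np.sum((tb == s) & (eb == 1)))
        d = d1 + d2
        if ntot == 0 or d == 0:
            continue
        e1 = d * n1 / ntot
        obs += (d1, d2)
        exp += (e1, d - e1)
        o_minus_e += d1 - e1
        if ntot > 1:
            var += n1 * n2 * d * (ntot - d) / (ntot**2 * (ntot - 1))
    if var == 0.0:
        chi = 0.0
    else:
        chi = o_minus_e**2 / var
    p = float(stats.chi2.sf(chi, df=1))
    return LogRankResult(float(chi), 1, p, obs, exp)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxFit:
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: np.ndarray  # 95% Wald, hazard-ratio scale
    ci_upper: np.ndarray
    p_values: np.ndarray  # two-sided Wald
    log_likelihood: float
    score_chi2: float  # score test of beta = 0, df = len(names)
    ties_method: TiesMethod
    converged: bool
    n_iterations: int
    n: int
    n_events: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se(coef)": self.se,
                "HR": self.hazard_ratios,
                "HR 95% lower": self.ci_lower,
                "HR 95% upper": self.ci_upper,
                "p": self.p_values,
            },
            index=list(self.names),
        )


def _cox_loglik_grad_hess(beta, t, e, X, ties: TiesMethod):
    """Log partial likelihood, gradient and Hessian at beta.

    Arrays are pre-sorted by ascending duration. Risk-set sums are suffix
    sums; tied event times are handled by Efron's average-removal correction
    (Breslow: no correction).
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -700, 700)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])
    # suffix sums: S*[i] = sum over j >= i
    S0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    S1 = np.concatenate([np.cumsum(wx[::-1], axis=0)[::-1], np.zeros((1, p))])
    S2 = np.concatenate([np.cumsum(wxx[::-1], axis=0)[::-1], np.zeros((1, p, p))])

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # block [i, j) shares one time; events within it are the tie set
        ev = np.nonzero(e[i:j])[0] + i
        d = ev.size
        if d:
            s0r, s1r, s2r = S0[i], S1[i], S2[i]
            ll += float(eta[ev].sum())
            grad += X[ev].sum(axis=0)
            if ties == "efron" and d > 1:
                s0d = w[ev].sum()
                s1d = wx[ev].sum(axis=0)
                s2d = wxx[ev].sum(axis=0)
            else:
                s0d = 0.0
                s1d = np.zeros(p)
                s2d = np.zeros((p, p))
            for l in range(d):
                phi = l / d if (ties == "efron" and d > 1) else 0.0
                den = s0r - phi * s0d
                num1 = s1r - phi * s1d
                num2 = s2r - phi * s2d
                ll -= np.log(den)
                xbar = num1 / den
                grad -= xbar
                hess -= num2 / den - np.outer(xbar, xbar)
        i = j
    return ll, grad, hess


def cox_ph(
    durations,
    events,
    covariates,
    names: Sequence[str] | None = None,
    ties_method: TiesMethod = "efron",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Maximizes the log partial likelihood (Efron correction for ties by
    default) starting from beta = 0, with step-halving when a step would
    decrease the likelihood. Standard errors come from the inverse observed
    information at the optimum; 95% CIs are exp(beta +- 1.96 se).

    Raises :class:`DegenerateInputError` when no events exist or a covariate
    is constant, and :class:`ConvergenceError` on a singular information
    matrix or a monotone likelihood (complete separation).
    """
    t = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=int)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if t.shape[0] != n or e.shape[0] != n:
        raise InputError("durations, events and covariates must align")
    if ties_method not in ("efron", "breslow"):
        raise InputError(f"unknown ties method {ties_method!r}")
    if e.sum() < 1:
        raise DegenerateInputError("Cox model requires at least one event")
    if np.any(np.ptp(X, axis=0) == 0):
        raise DegenerateInputError("all-constant covariate in Cox design")
    if names is None:
        names = tuple(f"x{k}" for k in range(p))
    names = tuple(names)

    order = np.argsort(t, kind="stable")
    t, e, X = t[order], e[order], X[order]

    # center covariates for numerical stability; beta is unaffected
    xbar = X.mean(axis=0)
    Xc = X - xbar

    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_grad_hess(beta, t, e, Xc, ties_method)
    info0 = -hess
    score_chi2 = _score_statistic(grad, info0)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        info = -hess
        try:
            cond = np.linalg.cond(info)
        except np.linalg.LinAlgError:  # pragma: no cover
            cond = np.inf
        if not np.isfinite(cond) or cond > 1e12:
            raise ConvergenceError("singular information matrix (collinear covariates)")
        delta = np.linalg.solve(info, grad)
        step = 1.0
        for _ in range(30):
            beta_new = beta + step * delta
            ll_new, grad_new, hess_new = _cox_loglik_grad_hess(
                beta_new, t, e, Xc, ties_method
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-13:
                break
            step /= 2.0
        else:  # pragma: no cover
            raise ConvergenceError("step-halving failed to improve likelihood")
        improved = ll_new - ll
        beta, ll, grad, hess = beta_new, ll_new, grad_new, hess_new
        if np.max(np.abs(beta)) > 50:
            raise ConvergenceError(
                "coefficients diverging: monotone partial likelihood "
                "(complete separation)"
            )
        if abs(improved) < tol and np.max(np.abs(grad)) < np.sqrt(tol):
            converged = True
            break

    # On a monotone partial likelihood the optimizer settles on the plateau
    # with an absurd coefficient; treat that as separation, not convergence.
    if np.max(np.abs(beta)) > 20:
        raise ConvergenceError(
            "coefficient magnitude implausible: monotone partial likelihood "
            "(complete separation)"
        )
    info = -hess
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise ConvergenceError("singular information matrix at optimum")
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    hr = np.exp(beta)
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hazard_ratios=hr,
        ci_lower=np.exp(beta - 1.959963984540054 * se),
        ci_upper=np.exp(beta + 1.959963984540054 * se),
        p_values=pvals,
        log_likelihood=float(ll),
        score_chi2=float(score_chi2),
        ties_method=ties_method,
        converged=converged,
        n_iterations=n_iter,
        n=n,
        n_events=int(e.sum()),
    )


def _score_statistic(grad0: np.ndarray, info0: np.ndarray) -> float:
    try:
        return float(grad0 @ np.linalg.solve(info0, grad0))
    except np.linalg.LinAlgError:
        return float("nan")


# ---------------------------------------------------------------------------
# Study-level fits on a retention table
# ---------------------------------------------------------------------------

IOS_COVARIATE = "platform_iOS"
RESIDENT_COVARIATE = "resident_physician"


@dataclass(frozen=True)
class StudyResults:
    """Per-stream Cox fits, pairwise log-rank tests, and KM curves for the
    stream / platform strata of a retention table."""

    cox: dict
    logrank: dict
    km: dict


def _design(table: pd.DataFrame) -> tuple[np.ndarray, tuple[str, str]]:
    ios = (table["platform"] == "iOS").to_numpy(dtype=float)
    res = (table["occupation"] == "resident_physician").to_numpy(dtype=float)
    return np.column_stack([ios, res]), (IOS_COVARIATE, RESIDENT_COVARIATE)


def fit_study_models(table: pd.DataFrame, univariable: bool = False) -> StudyResults:
    """Run the study's comparisons on a retention table.

    Per stream: a Cox model with the iOS indicator and the resident-physician
    indicator (jointly by default; ``univariable=True`` fits each factor in
    its own model). Log-rank tests: passive vs active overall, and Android vs
    iOS within each stream. KM curves per stream and per stream x platform.
    """
    required = {"stream", "duration_days", "event", "platform", "occupation"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"retention table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise InputError("empty retention table: no records")
    cox: dict = {}
    km: dict = {}
    logrank: dict = {}
    for stream in ("passive", "active"):
        sub = table[table["stream"] == stream]
        if len(sub) == 0:
            continue
        d = sub["duration_days"].to_numpy(float)
        e = sub["event"].to_numpy(int)
        X, names = _design(sub)
        if univariable:
            cox[stream] = {
                name: cox_ph(d, e, X[:, [k]], names=(name,))
                for k, name in enumerate(names)
            }
        else:
            cox[stream] = cox_ph(d, e, X, names=names)
        km[stream] = kaplan_meier(d, e)
        for platform in ("Android", "iOS"):
            mask = (sub["platform"] == platform).to_numpy()
            if mask.any():
                km[(stream, platform)] = kaplan_meier(d[mask], e[mask])
        a = (sub["platform"] == "Android").to_numpy()
        if a.any() and (~a).any():
            logrank[f"platform_within_{stream}"] = log_rank(
                d[a], e[a], d[~a], e[~a]
            )
    p = table[table["stream"] == "passive"]
    a = table[table["stream"] == "active"]
    if len(p) and len(a):
        logrank["passive_vs_active"] = log_rank(
            p["duration_days"].to_numpy(float), p["event"].to_numpy(int),
            a["duration_days"].to_numpy(float), a["event"].to_numpy(int),
        )
    return StudyResults(cox=cox, logrank=logrank, km=km)


def km_from_table(table: pd.DataFrame) -> SurvivalCurve:
    return kaplan_meier(
        table["duration_days"].to_numpy(float), table["event"].to_numpy(int)
    )
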