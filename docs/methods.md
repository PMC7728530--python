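# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind the package, in the order the pipeline runs.

## Geofence dwell-time detection

The detector is a two-state hysteresis machine over the fix stream of one
user. Distances are haversine great circles on a sphere of radius 6371.0 km;
at sub-kilometre scales the spherical error is far below GPS noise. A fix is
in range when its distance to the nearest registered workplace (≤ 5 per
user) is at most `radius_km` (default 1.0). The boundary counts as in range
— a closed ball. This is an arbitrary but fixed choice; with floating-point
distances the measure-zero boundary case never matters in practice.

**Confirmation ("consecutive 30 minutes").** A session opens when a run of
in-range fixes with no out-of-range fix and no trace hole of
`confirm_min` (default 30 min) inside spans ≥ `confirm_min` from its first
to its current fix; the session start is assigned retroactively to the
run's first fix. At the nominal 10-minute sampling this requires four
fixes. The retroactive start matches the intended behaviour of the app
being modelled: a user entering the fence at 08:50 gets credited from
08:50, not from the 30-minute confirmation point.

**Closing.** While a session is open, it closes at the last in-range fix
when either (a) the run of out-of-range fixes since that fix spans
≥ `confirm_min` (measured first-out to current-out, so an excursion whose
fixes span < 30 min never splits a session), or (b) two consecutive fixes
are more than `confirm_min` apart — a hole in the trace. Holes are treated
as absence rather than presence: with no evidence the user stayed, the
conservative reading is to close. A session still open when the trace ends
is closed at its last in-range fix and flagged (`open_at_end`); the data
cannot distinguish "still at work" from "stopped recording".

**Multiple workplaces.** Being in range of *any* workplace continues one
session; overlapping fences are not attributed per workplace (the nearest
workplace is reported for bookkeeping only), because only total work hours
feed the downstream analysis.

**Days and overtime.** Calendar-day splitting uses the user's local
timezone, default Asia/Taipei (UTC+8) — the deployment market. Sessions
crossing midnight contribute to both days. Overtime is the signed
difference total − scheduled; undertime is meaningful and not clamped.

## Churn construction

Durations are whole days with day 0 the registration date; uploads are
bucketed to local calendar days. A "28-day period without any upload"
means 28 whole silent days: consecutive upload days d < d′ open a churn at
d iff d′ − d − 1 ≥ 28, and the trailing gap churns iff
cutoff − d_last ≥ 28, i.e. the silence completes inside the observation
window. Otherwise the user is censored at the cutoff with duration
cutoff − registration. Re-entries after a completed silence are ignored —
the earliest qualifying silence wins.

The churn date is anchored at the last upload before the silence
(`churn_anchor="last_upload"`), so a user who uploads once and vanishes has
duration 0. The alternative anchor (`gap_start`, the first silent day)
shifts every churned duration by +1 and is exposed as a flag; nothing
downstream depends on the choice beyond that shift.

One asymmetry of this definition is worth knowing: lengthening the
observation window can *reveal* that a user censored earlier had in fact
already stopped uploading, so a censored duration may shrink (while
flipping to an event) as the cutoff grows. Observed churn times are
immutable. The property tests assert exactly this behaviour.

A user included in the cohort but with zero uploads in one stream (e.g.
passive-only users never answering surveys) is anchored at the
registration day for that stream: duration 0 with an event as soon as a
full silent period fits before the cutoff.

## Survival statistics

All three estimators are implemented directly and cross-checked against
independent libraries in the test suite.

*Kaplan-Meier*: product-limit over distinct event times; censored
durations only shrink later risk sets; Greenwood's formula for the
variance, with the convention Var = 0 once S reaches 0. Evaluation is
right-continuous with S = 1 before the first event.

*Log-rank*: two-sample O − E statistic with the hypergeometric variance at
each pooled event time (times where the pooled risk set has fewer than two
subjects contribute no variance), χ² with 1 df, two-sided p. No
multiple-testing correction is applied anywhere.

*Cox*: Newton-Raphson from β = 0 on the log partial likelihood, covariates
centred for conditioning, step-halving on any non-increase, convergence
when the likelihood change falls below `tol` (default 1e-9) with a small
gradient. Ties use Efron's correction by default — durations are whole
days, so ties are guaranteed — with Breslow available for comparison
against Breslow-only references. Standard errors come from the inverse
observed information at the optimum; the score statistic at β = 0 is also
reported (without ties and with one binary covariate it equals the
log-rank χ², a classical identity the tests verify to 1e-8). Degenerate
designs raise: no events or constant covariates (`DegenerateInputError`),
exactly collinear columns (singular information), and monotone likelihoods
from complete separation, detected as a coefficient exceeding 20 in
magnitude (hazard ratio ~5·10⁸ — far beyond anything estimable at these
sample sizes) or diverging past 50 during iteration.

The study-level fit mirrors the published analysis: per stream, one Cox
model with two indicators — iOS (vs Android) and resident physician (vs
all other occupations) — fitted jointly by default. The published table
does not state whether the two factors were fitted jointly or separately,
so a `--univariable` flag fits them one at a time instead; the ambiguity
is surfaced rather than resolved. Log-rank comparisons: passive vs active
overall, and Android vs iOS within each stream.

## Synthetic cohorts

The generator emulates the deployment's study conditions: n = 342 users;
registrations uniform over 2018-08-01..2019-01-31 with cutoff 2019-03-31
(so every user has ≥ 59 days of follow-up and a completed first-month
silence is always observable); age normal 33.76 (SD 7.01) clipped to
[20, 59]; 224/342 male; occupations at the reported margins — 128/342
resident physicians, 286/342 medical staff. Only those totals are
published, so the split of the 158 non-resident medical staff (60 visiting
staff / 40 medical students / 58 nurses) is an invented but fixed default.

**Churn model.** Per (stream × platform), a piecewise-exponential daily
hazard on [0,7), [7,28), [28,∞). The first two rates come in closed form
from the published one-week/one-month retention readouts
(λ₁ = −ln S(7)/7, λ₂ = −ln(S(28)/S(7))/21); the post-month rate continues
at λ₂, a modelling choice — nothing is published beyond one month. The
default Android share is 0.32, the unique mixing weight that reconciles
the published overall readouts with the per-platform ones at both horizons
and in both streams (e.g. (46.7 − 36.2)/(69.2 − 36.2) ≈ 0.318); that all
four readout pairs give the same weight is a useful internal-consistency
check of the calibration. Occupation effects enter as hazard multipliers
and default to 1 — the platform-specific rates already absorb the marginal
structure, and occupation effects are switched on explicitly in the
recovery studies.

**Day discretization.** Churn is simulated in continuous time T and the
last upload day is ⌈T⌉: the user stays active through the day in which
their continuous retention time ends. This makes P(last day > d) = S(d)
exactly at whole days d, so the pipeline's KM readouts at days 7 and 28
are unbiased for the calibration anchors; flooring instead would shift the
day-7 readout down by a factor e^(−λ₂) (about 1.2 points for the passive
stream), an artifact of discretization rather than of the estimators.

**Active cadence.** Real active data are monthly survey submissions, and a
monthly cadence interacts degenerately with the 28-day rule: consecutive
first-of-month uploads are 28–31 days apart, so the silence between them
completes for every month except into a 28/29-day February and almost
every user "churns" at their first survey. The generator therefore
defaults to persistence mode — active uploads daily while actively
retained, with the active-stream hazards carrying the (much faster)
active decay — which reproduces the published steep active retention
honestly. The literal monthly cadence is implemented
(`active_cadence="monthly"`) and tested, but under it ground-truth churn
days are not recoverable from the logs by construction.

**Traces.** Commuter traces put the user at home, at work during the
scheduled span, or linearly in between during a 30-minute commute, with
fixes every 10 minutes over 06:00–22:00, isotropic Gaussian position noise
(default SD 30 m) and independent dropout (default 2%). Weekends are days
off. This emulates the geometry the geofence cares about — dwell and
boundary crossings — not road networks or realistic mobility, so passing
trace tests says nothing about e.g. multi-stop commutes or urban-canyon
GPS bias.

**What the generator does not emulate.** Real upload logs have partial-day
outages, OS-dependent background-refresh failures, device changes and
re-installs; real churn need not be piecewise-exponential, and real
platform/occupation effects need not be proportional. Passing round-trip
tests demonstrates that the pipeline recovers the parameters of *this*
generative family at the study's sample size — not that the deployment's
estimates were correct.

## Replication studies and problem sizes

The calibration and recovery studies use 200 replicates at n = 342: the
KM round trip averages day-7/day-28 readouts over replicated cohorts
(per-replicate SE 1–3 points, so the mean is determined to ~0.1–0.2
points), and the Cox study simulates continuous-time exponential churn at
the published hazard ratios (platform HR 2.688 in the passive stream,
resident HR 0.119 in the active stream, the companion covariate of each
stream at its published value) with uniform administrative censoring over
the cohort's 59–242-day follow-up range, checking mean-HR recovery within
10% and nominal 95% Wald coverage. Continuous durations are used there
deliberately: the target is the estimator, and day-grouping attenuation is
a property of the discretization, not of the fit. Library cross-checks run
on 10³ random small datasets per estimator. All randomness flows from
explicit integer seeds; identical configuration and seed give
byte-identical CSV outputs.

## Known limitations

- The day-bucketing of uploads assumes registration and upload timestamps
  share one timezone (the deployment is single-market).
- The Cox implementation covers right censoring only: no stratification,
  time-varying covariates, robust variances, or proportional-hazards
  diagnostics.
- The log-rank test is two-sample; the published three-way occupation
  structure is analysed only through the resident-vs-others collapse.
- Monthly-cadence active logs make the 28-day rule nearly vacuous (see
  above); any "fairer" active-retention definition is out of scope.
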