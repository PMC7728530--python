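# dwellsurv

Survival analysis of mobile-app user retention, driven by passive GPS
sensing. The package implements the full analysis pipeline of a work-hours
app deployed to hospital staff: a geofence algorithm that turns background
GPS fixes into daily work hours (the app's *passive* data stream), monthly
survey submissions (the *active* stream), a churn definition based on
28-day upload silences, and survival statistics — Kaplan-Meier, log-rank,
Cox proportional hazards — written from first principles. Because the
deployment's raw logs are not public, a calibrated synthetic-cohort
generator with known ground-truth churn makes every stage testable end to
end.

It is aimed at digital-phenotyping and mHealth researchers who want to
quantify how long users keep feeding data to a passive-sensing app, and at
anyone who needs a compact, dependency-light survival stack they can audit.

## The model

**Geofenced work sessions.** A fix at time *t* is *in range* when its
haversine distance to any of the user's (at most five) registered
workplaces is ≤ 1 km (closed ball). With fixes nominally every 10 minutes,
a session opens once an uninterrupted in-range run spans ≥ 30 minutes —
the start is assigned retroactively to the run's first fix — and closes at
the last in-range fix before an out-of-range (or missing-data) span of
≥ 30 minutes. Daily total hours are session time intersected with the
local calendar day; overtime = total − scheduled hours, signed.

**Churn.** Per stream, retention stops at the first date opening a 28-day
period with no upload; the churn time is the last upload day before that
silence (day 0 = registration). Users whose silence has not completed by
the study cutoff are right-censored there. Inclusion requires demographics
and at least one upload within 28 days of registration.

**Survival statistics.** For each group, the Kaplan-Meier estimator

S(t) = ∏_{tᵢ ≤ t} (1 − dᵢ/nᵢ)

with Greenwood variance; the two-sample log-rank statistic
(O − E)²/V ~ χ²₁ summed over pooled event times; and Cox regression
h(t|x) = h₀(t)·exp(x'β) fitted by Newton-Raphson on the log partial
likelihood with Efron tie handling (Breslow available), Wald intervals
exp(β ± 1.96·se).

**Synthetic cohorts.** Churn times are piecewise-exponential on day
intervals [0,7), [7,28), [28,∞), with per-(stream × platform) rates
obtained in closed form from published one-week/one-month retention
readouts (λ₁ = −ln S(7)/7, λ₂ = −ln(S(28)/S(7))/21), plus optional
multiplicative occupation effects. Commuter GPS traces (home/work
geometry, 10-minute sampling, position noise, dropout) exercise the
geofence stage.

## Worked example

Simulate the default 342-user cohort and run the whole chain:

```bash
dwellsurv simulate  --config config.json
dwellsurv workhours --config config.json   # GPS traces -> sessions, daily hours
dwellsurv retention --config config.json   # upload logs -> survival records
dwellsurv survive   --config config.json   # KM + log-rank + Cox + figures
dwellsurv report    --config config.json
```

with `config.json`:

```json
{
  "simulate": {"n_users": 342, "include_traces": true, "trace_days": 5, "trace_users": 5},
  "out": "demo/out",
  "seed": 7
}
```

The generated `report.md` ends with (seed 7):

```
| comparison              | chi-square | p        |
| platform_within_passive | 62.712     | 2.39e-15 |
| platform_within_active  | 32.082     | 1.48e-08 |
| passive_vs_active       | 95.109     | 1.8e-22  |

| stream  | covariate           | HR (95% CI)         | p        |
| passive | platform_iOS        | 2.749 (2.127-3.552) | 1.08e-14 |
| passive | resident_physician  | 0.803 (0.637-1.013) | 0.0644   |
| active  | platform_iOS        | 0.499 (0.393-0.635) | 1.44e-08 |
| active  | resident_physician  | 0.893 (0.714-1.117) | 0.322    |
```

Read that as: passive (GPS) uploads outlive active (survey) uploads
(log-rank χ² = 95.1); within the passive stream, iOS users churn ~2.7×
faster than Android users — the platform effect the generator's default
per-platform hazards encode — while the occupation effect is null by
default. The same numbers are available programmatically:

```python
>>> from dwellsurv import CohortConfig, generate_cohort, km_readouts
>>> km_readouts(generate_cohort(CohortConfig(seed=7)))
    stream platform    n        S7       S28
0  passive      all  342  0.467836  0.277778
1  passive  Android  109  0.743119  0.504587
2  passive      iOS  233  0.339056  0.171674
3   active      all  342  0.228070  0.046784
...
```

i.e. one-week passive retention 46.8% and one-month 27.8% for this seed —
the quantities the generator is calibrated to.

## Layout

```
src/dwellsurv/geofence.py    # haversine, geofence hysteresis, daily hours
src/dwellsurv/retention.py   # installation rule, exclusions, churn scan
src/dwellsurv/survival.py    # KM, log-rank, Cox (Efron/Breslow), study fits
src/dwellsurv/cohort.py      # calibrated synthetic cohorts + GPS traces
src/dwellsurv/pipeline.py    # run config, stages, figures, report
src/dwellsurv/cli.py         # the `dwellsurv` console script
docs/methods.md              # modelling assumptions and design choices
```
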