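# wearmob

Wearable-sensor analysis of compliance with tiered public-health
interventions. `wearmob` converts 5-minute smartwatch records (GPS fix,
step count, heart rate) into two daily mobility outcomes — the **fraction
of time spent at home** and **total steps/day** — aligns them with
country-specific COVID-19 intervention-level calendars, and quantifies the
effect of each escalation level with unadjusted summaries and an adjusted
random-intercept mixed model.

It is written for epidemiologists and biostatisticians working with
panel-style wearable deployments (here: two cohorts of asthmatic
schoolchildren in Cyprus and Crete, tracked February–April of 2019 and
2020). Because such data are privacy-sensitive, the package ships a
synthetic-cohort generator with known ground truth that emulates the study
conditions, so the entire pipeline is testable and demonstrable without any
download.

## The metric and the model

A day has 288 five-minute intervals. Each interval is classified against a
circular geofence of radius 100 m around the participant's residence using
great-circle distance: `AT_HOME`, `OUT_HOME`, or `MISSING` (no fix).
Missing intervals inherit the label of the most recent valid fix
(carry-forward, crossing midnight; leading gaps are back-filled). Then

```
fraction_home = (# AT_HOME intervals × 5 min) / 1440 min
total_steps   = Σ interval steps
```

Days with no heart-rate sample (watch not worn) and desert-dust-storm
advisory days are excluded. Level effects are estimated per site with the
linear mixed model

```
y_ij = β₀ + β_level·L_ij + β_wk·wk_ij + β_wk×level·(wk·L)_ij
     + β_age·age_i + β_male·male_i + β_yr·yr_ij
     + β_T·T_ij + β_H·H_ij + β_s·sin(2πd/P) + β_c·cos(2πd/P)
     + u_i + ε_ij ,   u_i ~ N(0, τ²),  ε_ij ~ N(0, σ²)
```

where `L` is the intervention level (categorical, level 0 = no measures as
reference), `u_i` a participant random intercept, and `P = 30.44` days a
monthly harmonic period. Estimation is REML (statsmodels `MixedLM`);
inference is Wald with normal critical values; level contrasts (each level
vs baseline and vs the previous level) are Bonferroni-adjusted and capped
at 1.

## Worked example

```python
import datetime as dt
from wearmob import (default_synthetic_config, simulate_cohort, process,
                     annotate, fit_mixed, level_means)
from wearmob.config import StudyWindow

cfg = default_synthetic_config(seed=42)
cfg = cfg.model_copy(update={"study_windows": [
    StudyWindow(year=2020, start=dt.date(2020, 2, 3), end=dt.date(2020, 4, 26))]})
for s in cfg.sites:
    s.n_participants, s.n_participants_prior_year = 15, 0

cohort = simulate_cohort(cfg)                                   # 5-min traces
res = process(cohort.intervals, cohort.participants,            # daily metrics
              dds=cohort.dds_days)
tab = annotate(res.daily_metrics, cohort.participants, cohort.weather)

cy = tab[tab.site == "Cyprus"]
print(level_means(cy, "fraction_home", site="Cyprus"))
fit = fit_mixed(cy, "fraction_home")
print(fit.terms)
```

prints (abridged):

```
 level   n  mean  ci95_low  ci95_high  p_vs_baseline
     0 482 0.466     0.456      0.476            NaN
     1 162 0.825     0.810      0.840            0.0
     2  84 0.856     0.835      0.877            0.0
     3 331 0.856     0.846      0.866            0.0

   term    coef     se  ci95_low  ci95_high  pvalue
level_1  0.4119 0.0097    0.3929     0.4308     0.0
level_2  0.4380 0.0124    0.4136     0.4624     0.0
level_3  0.4341 0.0072    0.4200     0.4482     0.0
weekend  0.1278 0.0090    0.1103     0.1454     0.0
wk_lvl1 -0.2102 0.0159   -0.2415    -0.1790     0.0
random-intercept var: 0.00218  residual var: 0.00639  n_obs=1059
```

Reading: children in the simulated Cyprus cohort spent ~47% of the day at
home before any measures and ~86% under lockdown; adjusted for weekends,
demographics and weather, each intervention level raised time at home by
41–44 percentage points (the generator's configured truths are
+41.4/+48.7/+45.2). The weekend effect is positive at baseline (+12.8
points — families are home on weekends) and reverses under lockdown
(`wk_lvl*` interactions ≈ −20 points: everyone is home on weekdays, and
permitted outings happen on weekends).

## Command line

```
wearmob run --config examples/demo.yaml --out-dir demo_out   # full pipeline
wearmob simulate --out sim_dir --seed 7                      # traces only
wearmob process  --intervals ... --participants ... --out daily.csv
wearmob annotate --daily ... --weather ... --out analysis.csv
wearmob infer    --analysis analysis.csv --out-dir tables/
```

`run` writes every stage output plus `manifest.json` (config hash, seed,
per-stage row counts, exclusion tallies, SHA-256 of every file); the same
config and seed reproduce identical bytes. The bundled
`examples/demo.yaml` (10 participants/site, 4 weeks) completes in a few
seconds.

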