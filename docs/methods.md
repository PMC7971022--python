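# Methods

## Problem and outcomes

`wearmob` analyses compliance with tiered COVID-19 public-health
interventions from consumer smartwatch data. Two cohorts of asthmatic
schoolchildren — one in Cyprus, one in Crete (Greece) — wore a GPS +
pedometer + heart-rate smartwatch that logs one record every 5 minutes.
Two daily outcomes are derived per participant:

* **fraction of time spent at home** — the share of the 288 five-minute
  intervals of a calendar day whose GPS fix lies inside a circular geofence
  of radius 100 m around the participant's residence. The denominator is
  always 1,440 minutes, regardless of record completeness.
* **total steps/day** — the sum of non-missing interval step counts.

The 100 m radius reflects the positional accuracy of consumer GPS
receivers; it is configurable (`radius_m`) and the boundary is inclusive
(a fix at exactly the radius counts as at home — the tie must break one way
and toward home is the deterministic choice consistent with the fence being
an accuracy allowance).

## Sensor processing

1. **Validation.** Timestamps must sit on the 5-minute grid; duplicate
   (participant, timestamp) rows keep the first occurrence and are counted
   in the log (cloud-sync duplicates are plausible; silent averaging is not
   auditable). Coordinates outside WGS84 ranges are rejected.
2. **Geofence classification.** Great-circle (haversine) distance on a
   sphere of radius 6,371 km against the participant's home coordinate:
   `AT_HOME` (≤ radius), `OUT_HOME` (> radius), `MISSING` (no fix).
3. **Carry-forward imputation.** Indoor environments block GPS, so missing
   fixes are informative. Each `MISSING` interval inherits the label of the
   most recent valid fix of the same participant, across midnight and with
   no cap on run length (the longest imputed run is logged). A leading run
   with no prior fix takes the label of the next valid fix. A participant
   with no valid fix anywhere is unresolvable; those days are excluded and
   tallied. Raw fixes are used — no smoothing or stay-point clustering.
4. **Wear detection.** A day counts as worn iff at least one heart-rate
   sample exists in its 24 h. Non-wear days are excluded.
5. **Exclusions.** Desert-dust-storm (DDS) advisory days are removed per
   site (the parent study issues behavioural advice on those days, which
   deliberately alters mobility). Every excluded participant-day lands in
   exactly one audit tally: non-wear, unresolvable, DDS, or weather gap.

Step totals sum whatever intervals report; there is no rescaling for
intervals with missing step counts, mirroring the fixed 24-h denominator
choice for the home fraction.

## Study-design covariates

Intervention calendars are built in for the two countries (escalation from
level 0, no measures, to level 3, stringent lockdown, during
February–April 2020) and overridable by YAML. Every 2019 date is level 0.
Each retained participant-day is annotated with: intervention level
(categorical, level 0 reference), weekend (Saturday/Sunday of the local
calendar), a 2020-vs-2019 year indicator, age, gender, site temperature
and relative humidity (linear interpolation across gaps ≤ 2 days, longer
gaps drop the day with a warning), and one sine/cosine harmonic pair
`sin(2πd/P), cos(2πd/P)` of the day-of-year `d`. The default period
`P = 30.44` days (a mean month) absorbs roughly-monthly periodic
variability; `P` is a logged configuration value, so an annual harmonic is
one flag away. Month fixed effects were the alternative reading; the
harmonic pair was chosen because it is smooth, 2-parameter, and
configurable.

## Inference

* **Unadjusted:** per-level means of pooled participant-days with
  normal-theory 95% CIs, a one-way ANOVA across levels, and pairwise
  pooled-variance t-tests Bonferroni-multiplied by the number of level
  pairs and capped at 1. Pooling ignores within-participant clustering by
  construction — that is what "unadjusted" means here; `n` is reported per
  level. Severity-stratified summaries reuse the same code path with a
  stratum argument.
* **Adjusted:** a linear mixed model per outcome and site,
  `y_ij = Xβ + u_i + ε_ij` with a participant random intercept
  `u_i ~ N(0, τ²)`, fitted by REML (statsmodels MixedLM; REML is the
  conventional default for variance-component estimation). Fixed effects:
  level (3 dummies), gender, age, year, weekend, temperature, humidity,
  the harmonic pair, and weekend-by-level interactions. Inference is Wald
  with normal critical values, which yields the symmetric 95% CIs such
  studies print. Constant design columns (e.g. the year indicator in a
  single-year table) are dropped with a warning; genuinely collinear terms
  raise an error that names them. Rows with any missing covariate are
  list-wise dropped and counted. If the default optimizer does not produce
  a converged fit with finite standard errors, Powell/CG/Nelder–Mead are
  tried in turn; persistent failure raises rather than returning a silent
  result. A random-intercept variance estimated at the boundary (0) is
  flagged in the log.
* **Contrasts:** Wald contrasts of each level against baseline and against
  the previous level from the fixed-effect covariance, Bonferroni-adjusted
  over the emitted family and capped at 1.
* **Weekly series:** means per (site, year, study week), weeks being 7-day
  blocks anchored at February 3.

With `fix_zero_group_variance=True` the random-intercept variance is pinned
at zero; the marginal model is then exactly ordinary least squares and is
fitted as such. This is a diagnostic limit: on independent data the free
REML fit drives τ̂² to the boundary and reproduces the same coefficients.

## Synthetic cohort generator

The generator emulates the study conditions so every stage is testable
without real data: 53 Cyprus / 55 Greece participants in the main year,
39 / 52 in the prior year (the prior-year cohort is the leading subset of
the roster, so random intercepts persist across years), windows February 3
– April 26 of 2019 and 2020, 288 intervals/day.

Hierarchy:

1. **Participants:** age ~ U(6, 11), 57% male, homes scattered 0.5–8 km
   around the site reference point, asthma-eligibility flags at the
   site-specific published frequencies (at least one criterion is forced,
   matching the eligibility rule), and Gaussian random intercepts for both
   outcomes (SD 0.05 for the home fraction, 1,000 steps).
2. **Days:** expected outcomes are linear in level, weekend, age, gender,
   humidity and year plus day-level Gaussian noise (SD 0.08 / 2,200 steps).
   Default effect sizes are the published adjusted estimates: home-fraction
   level shifts +0.414/+0.487/+0.452 (Cyprus) and +0.143/+0.231/+0.320
   (Greece); step shifts −2,531/−3,638/−3,644 and −1,191/−2,337/−1,961;
   weekend effects +0.109/−1,002 at baseline, reversing under lockdown.
   Baselines (0.44/8,996 and 0.524/8,527) are calibrated to the main-year
   observed level-0 means, so the year effect (−1,560 / −2,791 steps for
   the main year) is applied as its negation to the prior year. The home
   fraction is clipped to [0, 1] and quantised to the 288-slot grid (the
   clipping biases high lockdown means by ~0.01 at these noise scales);
   steps are clipped at zero. Non-wear days are Bernoulli(0.10).
3. **Intervals:** a day's at-home occupancy is laid out as alternating
   home/away runs whose total home dwell equals the drawn daily value
   exactly, with the first home run anchored on the 00:00–06:00 sleep
   hours; away bout count is 1 + Poisson(1.2), capped at 6. The daily step
   total is spread over intervals by a multinomial whose rates are near
   zero while asleep at home. GPS fixes drop out with probability 0.55
   indoors vs 0.15 outdoors (indoor ≥ outdoor is enforced — indoor signal
   loss dominates for wrist receivers); present fixes land ≤ 80 m from
   home when at home and 150–2,000 m away otherwise, so classification
   against the 100 m fence is unambiguous. Heart rate is present per
   interval with probability 0.92 on worn days (one sample per worn day is
   guaranteed) and absent on non-wear days.

The drawn per-day truth (occupancy, steps, level, wear flag) is emitted for
oracle tests, and `simulate_cohort(..., daily_only=True)` returns it
without materialising intervals — the daily draw precedes the within-day
layout, so the two paths are identical in distribution at the day level.
Replicate studies of the day-level statistics (coverage, effect recovery)
use this path; the end-to-end identity test separately establishes that at
zero dropout the interval pipeline reproduces the daily truth exactly.

What the generator does **not** emulate: accelerometry waveforms or
heart-rate physiology (presence/absence only), multi-day battery gaps,
GPS position error correlated in time, school/holiday calendars beyond
weekends, within-family correlation, or any seasonal (harmonic) signal in
the outcomes. Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of its inference under the assumed
data-generating process, not robustness to every artefact of real traces.

Weather is an AR(1) daily series per site (autocorrelation 0.6) around
site-level means; DDS days are drawn uniformly per site-year at the
published counts (Cyprus 5/4 and Greece 1/2 for 2020/2019).

## Determinism and numerics

A single integer seed drives one `numpy` PCG64 generator for the whole
bundle; identical (config, seed) reproduces identical CSV bytes, recorded
as SHA-256 checksums in the run manifest together with per-stage row counts
and exclusion tallies. Coordinates are written at 6 decimals (~0.1 m),
weather at 1 decimal. The flat-earth metre-to-degree conversion used to
place fixes errs by far less than the 20 m margin between the 80 m home
placement bound and the 100 m fence.

## Known limitations

* Carry-forward imputation under indoor-dominant dropout clips the start
  of at-home runs (the last pre-gap fix is more often an away fix),
  biasing the observed home fraction down by ~2–3 percentage points at
  high occupancy in the default configuration. The real study shares this
  property; the adjusted level effects are recovered without bias because
  the generator's truth path is used for calibration studies.
* Observed per-level means are not expected to match the adjusted level
  effects added to baseline: weekend reversal, weather and demographic
  composition shift the pooled means, exactly as in the published tables.
* The unadjusted ANOVA treats participant-days as independent; its
  p-values are anti-conservative under clustering and are reported only as
  the conventional "unadjusted" companion to the mixed model.
* Wald (z) intervals ignore the finite number of participants; for
  between-participant terms with ~25 clusters the empirical coverage in
  simulation is ~93–96%.
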