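# Methods

`oryxhr` models the full measurement chain of subcutaneous heart-rate
biologging in a captive herd of scimitar-horned oryx — from the raw ECG
the device sees, through its automatic beat detection, to the hourly
statistical analysis of what drives heart rate. Every stage is
exercised on synthetic data with known ground truth, so each claim the
pipeline makes can be checked against the generating parameters.

## The sensing model and why it oversenses

Bovid hearts produce a tall ventricular repolarization wave (T) a long
ST interval after the QRS complex. An automatic detector tuned for
human ECG can classify that T wave as a second ventricular
depolarization and double-count every beat.

The simulator reduces the proprietary device algorithm to its two
documented controls:

* a **sensing threshold** (default 0.15 mV, the R-wave amplitude floor
  used when positioning the implant): a ventricular sense fires at an
  upward threshold crossing, `v[k-1] < θ ≤ v[k]`;
* a **blanking interval** `b` (100–500 ms; the device setting ranged
  150–300 ms): after a sense, no new sense can fire for `b` ms.

With the synthetic morphology (QRS 0.3 mV, T 0.2 mV at +250 ms) the T
crossing falls ~220–270 ms after the QRS sense, so `b = 300 ms`
suppresses it while `b = 150 ms` admits it. The device rate is
60000 / mean inter-sense interval (ms); double counting alternates
~250/750 ms intervals, whose mean is half the RR interval, so the
reported rate doubles exactly — the mechanism behind the observed
accuracy jump when the blank interval was raised to 300 ms. Episode
flags use inclusive thresholds: tachycardia at rate ≥ 125 bpm,
asystole at an inter-sense gap ≥ 4.5 s.

The ECG itself is a sum of Gaussian bumps (QRS σ = 12 ms, T σ = 25 ms)
plus white noise and optional short noise bursts. This is deliberately
not a physiological ECG simulator: the only features that matter for
the failure mode under study are relative amplitudes and the R-to-T
delay. RR intervals are jittered with a Gaussian truncated at ±3 SD so
beats stay ordered.

## Accuracy validation

Validation mirrors the field procedure: R-peaks are detected on each
10-s strip (local maxima above a height floor, separated by at least
250 ms, larger peak wins among conflicts), the expected rate is
60000 / mean RR, and a strip is *accurate* when
|observed − expected| / expected < 0.10, strictly — a relative
difference of exactly 10% fails. The denominator is the expected
(ECG-validated) rate, the reference standard. Percent columns round
half-up to integers to match the convention of the published table,
whose per-animal validated/accurate counts ship with the package as
input data (`validate.STUDY_VALIDATION_COUNTS`). Summaries also report
the pooled shares of strips within 5% and 10% and the adjusted R² of
an OLS regression of observed on expected rate.

## Preprocessing

* **Clock drift.** Device clocks err by an affine law
  (`device = true + offset + rate·days`). Paired (device, reference)
  times from download events are fitted by least squares
  (`reference = slope·device + intercept`, device times centered
  before regression for numerical stability at epoch scale) and the
  line is applied to every timestamp; an affine error inverts exactly.
  The pipeline then rounds corrected times to the nearest second,
  because device logs are second-resolution and sub-millisecond
  residue would otherwise push hour-boundary records into the wrong
  bin.
* **Filters.** Keep 2-min records with blank setting ≥ 300 ms and
  HR ≥ 30 bpm (exclusion below 30 is strict: a record at exactly
  30 bpm survives). Idempotent by construction.
* **Aggregation.** Hour bins are left-closed, right-open on a fixed
  local clock with no daylight-saving shifts; boundary records go to
  the later hour. Hourly HR is the arithmetic mean of the hour's 2-min
  averages; hours with no record carry a missing mean and are dropped
  from modeling, never imputed. Hourly activity sums the hour's four
  15-min values (0–60 min); an hour with zero activity is a *resting*
  hour, the resting-heart-rate proxy. Activity intervals off the
  15-min grid by more than 1 s raise a warning and are assigned to
  their containing hour.

## Environmental covariates

* **Photoperiod** uses the CBM day-length model (solar declination
  from day-of-year; day length from latitude and declination) with the
  50-arcminute sunrise/sunset convention (p = 0.8333°), matching the
  standard photoperiod function used in movement ecology; the package
  value for the study latitude (38.89292°N) on the June solstice,
  14.90 h, agrees with an independent evaluation of that function.
  Latitudes beyond ±66.5° are rejected rather than given polar-day
  handling.
* **Seasons** are astronomical, from a built-in solstice/equinox table
  for 2018–2021 (the deployment window); each season starts on its
  boundary date, and dates before the March equinox belong to the
  winter that began the previous December.
* **Temperature** is averaged from 30-min records to hours and
  converted to Fahrenheit (avoiding negative values for the spline
  fits); hours with a single half-hour value are flagged partial, and
  gaps propagate as missing.

## The additive model

Hourly heart rate for animal *i* at hour *t* is modeled as

    hr_it = β₀ + f₁(activity_it) + f₂(hour_t) + season_t
            + f₂ₛ(hour_t) + f₃(temp_t) + u_i + ε_it

with Gaussian errors and identity link. Terms:

* smooths `f` are **natural cubic regression splines** with knots at
  quantiles of the covariate and basis dimension equal to the
  requested degrees of freedom (defaults: activity 3, hour 6,
  temperature 3, day length 3). A regression-spline basis of dimension
  d is the zero-penalty member of the penalized family that attains
  exactly d effective df, so the target edf is hit without a penalty
  search. Basis columns are centered over the data, making each
  smooth's fitted values sum to zero (identifiability). Variables with
  too few distinct values degrade to a linear column.
* `season` uses sum-to-zero (effects) coding; the hour-by-season
  interaction `f₂ₛ` is a set of per-season deviation smooths from the
  shared hour smooth, coded to sum to zero across seasons.
* `u_i` is a per-animal **random intercept**, implemented as
  ridge-penalized group indicators with weight λ = σ²/τ². The two
  variances are estimated by Schall's fixed-point iteration:
  σ̂² = RSS/(n − edf), τ̂² = ‖b‖²/edf_b, λ updated until convergence
  (λ clamped to [1e−8, 1e10]; a degenerate ‖b‖ → λ at the cap).
* Hour enters as a non-cyclic smooth over 0–23 — the 23→0 wrap falls
  in the overnight trough, where little structure is lost; a cyclic
  basis was considered and left out for parity with the conventional
  cubic-spline term.

The log-likelihood is the Gaussian ML value at the fitted residuals,
`edf` is the trace of the hat matrix (fixed columns plus shrunken
random intercepts), and `AIC = −2·logLik + 2·edf`. Generalized R² is
`1 − exp((2/n)(logLik_null − logLik))` against the intercept-only
Gaussian likelihood. Coefficient tables report, for each smooth, the
coefficient of its linear basis component (directional only — the
curve is the estimand; partial-effect tables give the full curve with
pointwise standard errors from the Bayesian covariance σ²A⁻¹).

The original analysis fitted these models in a location-scale-shape
framework with a four-parameter (Johnson's SU) response; this package
deliberately uses a Gaussian response. The skew/kurtosis parameters do
not change which covariates matter or the shape of the partial
effects, which is what the model ladder and the recovery tests are
about; published coefficient magnitudes under the four-parameter
family are therefore treated as directional, not exact, references.

**Model ladder.** Nine nested specifications (`hrm0` intercept +
random effects, up to `hrm8` activity + hour×season + temperature +
random effects) are fitted on identical rows (rows missing any
variable used by any spec are dropped once) and compared by AIC; a
failing spec is marked and the comparison proceeds.

**Diagnostics.** Residual ACF is computed within animal (series
ordered by time, per-animal ACFs averaged with length weights) and on
the pooled concatenated residuals — both are reported because the
convention is not fixed. The subsample sensitivity check refits on a
uniform without-replacement sample of 500 rows per animal and reports
side-by-side coefficients with a standardized difference. For nested
samples the null variance of (full − sub) is se_sub² − se_full²; when
a coefficient's SE is dominated by shared between-animal structure
(the intercept) that difference degenerates and the subsample SE is
used as the scale instead. With ~16 coefficients the maximum
standardized difference exceeds 2 regularly under exact consistency,
so agreement is asserted as all |z| < 4 with at least 80% below 2,
plus sign agreement for clearly significant terms.

## The synthetic-data generator

The long-term generator is the package's definition of the study
conditions. Per animal and 2-min slot:

    HR = baseline_i + season + circadian + activity + temperature + AR(1),

floored at 25 bpm so the 30-bpm filter has records to remove.

| parameter | default | rationale |
|---|---|---|
| animals | 6 | the six usable (left-implant) subjects |
| baseline mean ± between-animal SD | 60.3 ± 5 bpm | pooled mean of the herd; ~12 bpm spread between individuals |
| circadian amplitude | 7 bpm | dawn-to-dusk rise of 14–17 bpm peak-to-trough |
| circadian peak hour | winter 16, spring/fall 17, summer 18 | peak near dusk, later in summer |
| season offsets | winter +2.5, spring +1.5, summer −2.5, fall −1.5 bpm | higher winter/spring; ~5 bpm inactive-hour winter–summer gap |
| activity effect | 10 bpm at a fully active hour, linear in min/60 | reported activity-dependent elevation |
| temperature steps | +2 bpm below 20 °F, −2 bpm above 80 °F | elevation at cold extremes, depression at heat |
| AR(1) on the 2-min grid | φ = 0.7, marginal SD 8 bpm | reproduces residual serial dependence |
| activity profile | hourly rates peaking at 17–18 h, care bumps at 8 h and 14–15 h, scaled per season | daily totals 60/151/214/107 min (winter/spring/summer/fall) |

Activity is drawn per 15-min interval as Binomial(15, p) from the
hourly rate profile times the season multiplier; the HR term uses the
*drawn* minutes of the interval containing each 2-min slot (15 min =
7.5 slots, so the mapping is by containing interval, not a fixed
repeat). Baseline draws are centered so the herd mean equals
`baseline_mean` exactly, and the season, activity and temperature
components are centered over the simulated window — `baseline_mean`
is then the pooled mean heart rate by construction, while every
contrast and slope (what recovery tests measure) is unchanged. The
truth ledger records all generating coefficients, per-animal
baselines and the centering constants.

Ambient temperature is a seasonal sinusoid (mean 12.5 °C, amplitude
12 °C, coldest mid-January) plus a diurnal sinusoid (amplitude 6 °C,
warmest 15 h) plus N(0, 2 °C) noise on a 30-min grid — a mid-Atlantic
foothill climate with real winter cold snaps below −7 °C and summer
afternoons above 27 °C.

A separate hourly-grid generator (AR(1) noise with φ = 0.7 at the
*hourly* lag plus a 2.2-bpm circadian signal on a 5-bpm noise SD)
defines the residual-diagnostics scenario: null-model residuals then
show ACF ≈ 0.7 at lag 1 and a daily bump at lag 24. Note that AR(1)
noise on the 2-min grid does not survive hourly averaging (φ^30 is
negligible), so the lag-1 structure of hourly residuals in the main
pipeline comes almost entirely from the unmodeled circadian signal —
the diagnostics scenario makes the two sources explicit. Because the
circadian bump is smooth, "a peak at lag 24" is asserted as the lag
22–26 band exceeding the lag 10–14 trough (and lag 24 > lag 12): the
difference between lag 24 and its immediate neighbours is smaller
than sampling noise at any reasonable series length.

**What the generator does not emulate** — and hence what passing
tests do not show about real deployments: real ECG morphology and
electrode noise (only the amplitude/timing skeleton), reproductive
and management events, weather beyond smooth sinusoids, device
dropouts and transmission gaps, behavioral states beyond the binomial
activity profile, and any nonlinearity in the activity–HR relation
(the generator is linear, so recovery tests cannot detect smoothing
bias in a nonlinear regime).

## Problem sizes

The default study window is 6 animals × 120 days starting 2019-03-01
(≈ 518k 2-min records, 17,280 hourly rows) — 120 consecutive days can
span at most three astronomical seasons, and this start maximizes
seasonal contrast (winter 19 d, spring 93 d, summer 8 d). The
model-selection study uses 20 seeded replicates of that window; the
analysis scripts run a full year (2018-09-23 + 365 d) to cover all
four seasons. Effect recovery is summarized as: activity — 60× the
density-weighted least-squares slope of the activity partial effect
(extrapolating the spline to 60 min is unstable because fully active
hours are rare); circadian — half peak-to-trough of the shared hour
smooth; season — maximum absolute error of the sum-to-zero effects
against centered truth, relative to the truth's span.

## Known limitations

* The sensing model is a two-parameter caricature of proprietary
  firmware; it reproduces the documented phenomenology (blank-interval
  dependence, T-wave and noise oversensing), not the device.
* Smooth df are fixed per term, not selected; the ladder reproduces
  the published comparison structurally, not df-for-df.
* The Gaussian response cannot reproduce coefficient magnitudes
  published under a four-parameter response family.
* Season boundaries come from a fixed 2018–2021 ephemeris; other
  years need a table extension.
* The hourly analysis drops incomplete hours rather than modeling the
  missingness mechanism.
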