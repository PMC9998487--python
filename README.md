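# oryxhr

Heart-rate biologging analysis for a captive herd of scimitar-horned
oryx (*Oryx dammah*) — and a testbed for everyone who wants to trust an
implantable heart-rate logger in a bovid before deploying it in the
wild.

Subcutaneous cardiac monitors detect heartbeats with an automatic
threshold algorithm tuned for human ECG. In bovids, a tall T wave
after a long ST interval can be counted as a second beat
(*oversensing*), doubling the reported rate unless the device's
blanking interval is set long enough. This package implements the full
chain needed to quantify that problem and then use the data anyway:

1. **synth** — synthetic device data with known ground truth: 10-s ECG
   strips with bovid morphology, months of 2-min heart-rate and 15-min
   activity logs with circadian/seasonal/activity/temperature
   structure, ambient temperature, clock drift;
2. **sensing** — the device simulator (threshold crossing + blanking
   period), derived rate, tachycardia/asystole flags;
3. **validate** — RR-interval accuracy validation of device rates
   (<10% criterion, per-animal accuracy table, observed~expected
   regression);
4. **preprocess** — clock-drift regression, blank/HR filters, hourly
   aggregation, resting-hour extraction;
5. **environment** — photoperiod (CBM model), astronomical seasons,
   hourly temperature in °F;
6. **model** — Gaussian additive mixed models for hourly heart rate:

       hr ~ intercept + f(activity) + f(hour)*season + f(temperature)
            + (1 | animal)

   with natural cubic regression splines, sum-to-zero constraints,
   ridge random intercepts (Schall's iteration), an AIC model ladder,
   residual-ACF diagnostics and a 500-points-per-animal subsample
   sensitivity refit.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
simulated year (6 animals, 365 days from the September equinox); raw
device exports land in `scratch/run/`, summary tables in
`results/analysis/`.

```sh
python analysis/01_simulate_devices.py --seed 1
python analysis/02_validate_accuracy.py --seed 1
python analysis/03_preprocess_series.py --seed 1
python analysis/04_fit_models.py       --seed 1
python analysis/05_residual_diagnostics.py --seed 1
```

Accuracy validation (script 02) shows the blanking mechanism: with the
300-ms blank every strip passes the <10% criterion, with 150 ms every
strip fails because each beat is double-counted:

```
blank 300 ms: {'strips_validated': 60, 'strips_accurate': 60, 'r_squared_adj': 0.999993...}
blank 150 ms: 0/60 accurate (0%)
published counts: left-side validated total = 647, accuracy span 83-99%
```

Preprocessing (script 03) recovers the herd's baseline statistics from
the filtered 2-min records — pooled mean 60.3 bpm, higher heart rate in
active hours, seasonal daily-activity totals, and a warmer-blooded
winter at rest:

```
animal_id  mean_bpm  sd_bpm  min_bpm  max_bpm
    total      60.3    10.4     25.0    104.1
hourly HR, inactive hours: 57.1 bpm; active hours: 60.7 bpm; contrast 3.6 bpm
daily activity minutes by season: winter 60, spring 151, summer 213, fall 107
inactive-hour HR, winter 58.5 bpm vs summer 54.6 bpm
```

Model comparison (script 04) ranks the nine-model ladder by AIC; the
full model — activity, hour-by-season interaction, temperature, animal
random intercepts — wins, and the null model is worst:

```
model  edf      aic  daic
 hrm8 30.0 274930.7     0.0
 hrm7 21.0 277946.1  3015.4
 hrm6 18.0 278770.1  3839.5
 ...
 hrm0  6.0 344948.4 70017.7
best fit hrm8: edf=30.0, AIC=274931, generalized R2=0.800
activity effect at a fully active hour: 9.5 bpm   (generated: 10)
circadian amplitude (shared hour smooth): 6.7 bpm (generated: 7)
subsample refit (500/animal): max |standardized difference| = 2.64
```

Residual diagnostics (script 05) show why the subsample check matters:
null-model residuals on the hourly data carry strong serial structure
(ACF 0.73 at lag 1, a daily bump of 0.73 at lag 24), yet the
500-point-per-animal refit leaves the coefficient story unchanged.

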