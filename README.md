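# shockwatch

Early warning of septic shock from continuous vital signs, for researchers
who study wearable monitoring in emergency departments. Febrile but initially
stable ED patients are monitored two ways at once: a chest-worn device
streams a 250 Hz single-lead ECG and a 25 Hz respiration waveform, while
nurses record SBP, DBP, HR, RR and mental status (GCS) hourly for up to 6 h.
The question is whether models fed the continuous device data recognise
impending septic shock (vasopressor need to keep MAP ≥ 65 mmHg, within 24 h
of enrolment) earlier than the same models fed the hourly manual readings.

Because no such cohort is publicly available, the package ships a seeded
synthetic cohort generator with the statistical structure the analysis
needs — fever on arrival, ~16% shock prevalence, deterioration ramps before
shock, waveform artifacts, device-vs-manual measurement noise — and runs the
entire analysis end to end against it.

## What it computes

1. **Waveform filtering.** The ECG is sliced into QRS-centred *beat units*
   (unit *i* spans the midpoints between neighbouring R-peaks). A unit is
   excluded when its length exceeds 1.5× the median unit length or its
   extreme amplitudes exceed 2× the median per-unit extrema; excluded spans
   are bridged by carry-forward imputation onto a 1 Hz HR series. The
   respiration signal — after discarding samples under ECG-excluded spans —
   yields per-cycle rates RR = 60/Δt, with a cycle excluded when it falls
   below 0.5× or above 1.5× the previous valid rate.
2. **Fragments.** At each time point a 14-value vector: age, sex, arrival
   temperature, arrival SpO2 (static); SBP, DBP, HR, RR, GCS (dynamic); and
   the five deltas vs baseline. Manual fragments hourly; device fragments
   every 5 min with HR/RR replaced by the filtered device series.
3. **Models.** A *fragmented* model scores one fragment at a time (dense
   network); an *accumulated* model scores the history up to each time point
   (encoder + single-layer LSTM, causal by construction); plus a logistic
   baseline. Patient-level 6:2:2 train/validation/test split.
4. **Evaluation.** AUROC/AUPRC, sensitivity and specificity with
   patient-level bootstrap 95% CIs; alarm thresholds at maximum sensitivity
   subject to specificity > 0.9 (chosen on validation, frozen for test);
   censored time-to-first-alarm within a 6 h horizon (alarms later than 6 h
   are recorded as "> 6 h"); Bland–Altman limits of agreement
   (mean difference ± 1.96 SD) between device and manual HR/RR; permutation
   feature importance.

See `docs/methods.md` for the model details, parameter defaults and the
generator's assumptions.

## Worked example

```bash
python examples/04_full_pipeline.py
```

runs the whole chain on a 60-patient demo cohort and prints (numbers from
this exact config and seed):

```
60 patients, prevalence 28.3%

model        data     AUROC  AUPRC  sens  spec
fragmented   manual   0.654  0.694  0.46  0.96
fragmented   device   0.721  0.696  0.46  0.97
accumulated  manual   0.781  0.680  0.23  1.00
accumulated  device   0.887  0.835  0.32  1.00

earliness of detection (device vs manual, true positives):
  fragmented: median device alarm 92 min vs manual 120 min; summed difference +55 min
  accumulated: median device alarm 230 min vs manual 240 min; summed difference +65 min
```

Reading: the models rank the synthetic shock patients above the others
(AUROC on test fragments; at 12 test patients the numbers are noisy — at the
400-patient scale of `scripts/acceptance.py` all four combinations exceed
0.8), and the device-fed models cross their alarm thresholds earlier than
the hourly manual models — the 5-minute grid sees the deterioration ramp
between nurse visits. `examples/01–03` walk the
individual stages (filtering recovery, fragment/model mechanics, agreement
and thresholds). The same pipeline is available as a CLI
(`shockwatch run-all --seed 3 --out runs/demo`).

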