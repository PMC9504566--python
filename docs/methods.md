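# Methods

`shockwatch` re-implements, as a tested pipeline, an analysis of whether
continuous heart-rate/respiratory-rate monitoring from a chest-worn device
predicts septic shock earlier than hourly manual vitals in febrile
emergency-department patients. The original cohort is not public, so every
component runs against a synthetic cohort generator that reproduces the
*statistical structure* the analysis needs; all empirical statements below are
about what the code computes on those synthetic cohorts.

## Synthetic cohort

One patient is: static covariates (age, sex, arrival body temperature > 38 °C,
arrival SpO2), a per-minute ground-truth vital trajectory, hourly manual
readings (SBP, DBP, HR, RR, GCS) for up to 6 h, two waveforms (250 Hz
single-lead ECG, 25 Hz impedance respiration), and a binary septic-shock
outcome within 24 h with its event time.

* **Population.** Covariate distributions follow published descriptives of
  this setting: age ~ N(57, 19²) clipped to ≥ 18 years; 44% male; body
  temperature ~ N(38.64, 0.57²) truncated above 38.0 °C; SpO2 ~ N(96.8, 2.5²);
  monitoring duration ~ N(300, 100²) min truncated to [60, 360] (patients
  leaving early are simply censored); outcome prevalence 16.2%.
* **Trajectories.** Baselines: HR ~ N(105, 12²) bpm, RR ~ N(18.2, 2.7²),
  SBP ~ N(127, 18²), DBP ~ N(76, 10²) mmHg, GCS 15 (14 with probability
  0.05). Noise is AR(1) per minute (φ = 0.9; innovation SD: HR 2, SBP 3,
  DBP 2, RR 0.8). Shock patients drift piecewise-linearly from baseline to
  baseline + (HR +40, SBP −35, DBP −20, RR +8, GCS −2) over a 180-min lead
  time ending at the shock time (drawn U(240, 480) min), and additionally
  present slightly sicker at arrival (HR +8, SBP −8, RR +1.5). The
  presentation shift reflects that sepsis is usually already evolving on
  arrival; it is deliberately small (≤ 0.7 SD) so the outcome is not readable
  from the baseline alone. Everything is clamped to physiologic bounds
  (HR 30–220, RR 5–60, SBP 50–250).
* **Waveforms.** ECG beats are Gaussian-bump QRS complexes (SD 15 ms,
  amplitude 1) on a noisy baseline (SD 0.04), placed by integrating the
  commanded instantaneous rate; amplitudes are quantised to a 14-bit grid
  over ±5 units. Respiration is a quasi-sinusoid with slow amplitude wander.
  Beat-to-beat interval jitter defaults to 0.5 bpm equivalent (cycle jitter
  0.5 breaths/min): a chest patch measuring R-R intervals at rest is a
  low-noise instrument, and most of the device-vs-manual disagreement should
  come from the manual observation noise (HR 3, SBP 4, DBP 3, RR 1.5, applied
  to each manual reading).
* **Artifacts.** A configurable fraction of beats/cycles (default 5%) is
  corrupted: beat-train suppressions and flatline dropouts sized to swallow
  at least two events (so the length rule sees an unambiguously widened
  unit), and amplitude spikes at 3× the typical maximum. Motion spikes are
  the most common patch artifact and get half the probability mass;
  suppressions and dropouts share the rest. Ground-truth masks and event
  positions are stored for scoring only; the filtering code never reads them.
* **Determinism.** The cohort seed fans out through `SeedSequence.spawn`, one
  child per patient; a fixed seed reproduces the cohort bit-identically.
* **`strong_signal_config`.** End-to-end discrimination/earliness checks use
  a named variant (shock at 180–300 min, effect sizes ×1.75) in which the
  deterioration is unambiguous at the single-fragment level. These checks ask
  whether the pipeline finds a signal that is clearly there — they say
  nothing about effect sizes in real patients.

What the generator does **not** emulate: real ECG morphology (P/T waves,
arrhythmia), respiratory-cardiac coupling, non-monotone or relapsing
deterioration, treatment effects, missing manual readings, device detachment.
Passing tests therefore demonstrate correctness of the pipeline's mechanics
and directional behaviour, not clinical performance.

## Waveform filtering

R-peaks: band-pass 5–30 Hz (3rd-order Butterworth, zero-phase), squared and
smoothed (100 ms window); candidate maxima at a 200 ms refractory distance
are split into noise/QRS by an Otsu threshold on log-energy, and accepted
peaks are refined to the local maximum of a lightly smoothed raw signal
(edge peaks inside the filter's boundary transient are discarded). On clean
synthetic records the detector recovers > 99% of generator beats within
±20 ms.

Beat units tile the record: unit *i* spans the midpoints between neighbouring
peaks, edge units extend to the record ends. A unit is excluded when its
length exceeds 1.5× the median length, its maximum exceeds 2× the median of
per-unit maxima, or its minimum lies below 2× the median of per-unit minima.
Three choices deserve note:

* medians are computed once over the whole record, not in sliding windows;
* the amplitude rule's reference is the *median* of per-unit extrema —
  symmetric with the length rule and robust to the very outliers being
  tested; "twice as small" is read as twice as deep below a near-zero
  baseline;
* per-unit HR is 60 over the beat's preceding R–R interval (the first unit
  uses its following interval).

The 1 Hz HR series samples, at each second's start, the unit covering that
sample; seconds covered by excluded units take the most recent valid value
(carry-forward) and are flagged in an imputation mask, a leading invalid span
is backfilled from the first valid unit. The imputed fraction equals the
invalid-coverage fraction exactly, by construction.

Respiration is processed after the ECG: samples in ECG-excluded time spans
are discarded first; crests are local maxima of a 0.4 s-smoothed signal with
prominence ≥ 0.3 and ≥ 1 s separation (60 breaths/min ceiling). Per-cycle
rate is 60 / crest interval; a cycle is excluded when it overlaps a removed
span, falls outside 5–60 breaths/min, or deviates below 0.5× / above 1.5× the
previous *valid* rate (comparing to an excluded value would propagate
artifacts). The sequential rule has a failure mode: one wrongly accepted
half-rate cycle makes every true cycle look too fast, locking the chain.
After 5 consecutive rate-rule exclusions the chain therefore re-anchors on
the next plausible cycle; the bound is short enough that a wrong anchor
poisons at most ~15 s.

## Fragments

A fragment is 14 values: age, sex, arrival temperature, arrival SpO2 (static);
SBP, DBP, HR, RR, GCS (dynamic); and the five dynamic deltas against baseline.
Manual fragments sit on the hourly grid with the t = 0 reading as baseline.
Device fragments sit on a 5-minute grid; HR and RR are trailing-window medians
of the 1 Hz series (robust to residual artifacts), BP and GCS carry forward
from the most recent manual reading. Device HR/RR deltas are taken against
the t = 0 *device* values so that the two sources are internally consistent;
the carried manual values keep the manual baseline. Fragment counts are exact:
`floor(duration/60)+1` manual, `floor(duration/5)+1` device.

## Models

Two structures share one contract (fragments → risk in [0, 1] at each
fragment time):

* **fragmented** — a dense ReLU network (default 14→16→8→1) scoring each
  fragment independently. A 1-D convolution over the 14-vector was considered
  and rejected: the features are an unordered tuple with no translation
  structure for a kernel to exploit.
* **accumulated** — the same encoder per fragment feeding a single-layer LSTM
  (default hidden size 12) with a per-step sigmoid head. The recurrence makes
  the risk at time t depend only on fragments up to t; causality is a
  property test, not a convention.
* **logistic baseline** — scikit-learn logistic regression on fragments, a
  fully deterministic reference.

The networks are written in numpy (full-batch Adam, float64, seeded
initialisation) so that a fixed seed reproduces training bit-for-bit on any
platform; gradients are verified against finite differences in the test
suite. Training minimises class-weighted binary cross-entropy (weights
inversely proportional to class frequency; prevalence ≈ 16%) with early
stopping on validation AUROC (default patience 25, max 200 epochs). Every
fragment of a shock patient carries the patient-level positive label: the
outcome is defined per patient within 24 h, and no time-resolved labels
exist — which also means early pre-deterioration fragments of shock patients
are genuinely mislabelled, capping fragment-level AUROC below 1 by
construction. Features are z-scored with training-set statistics only.

Patients are split 6:2:2 at the patient level (validation and test each get
`floor(0.2 n)`, remainder trains), deterministically from a seed.

## Evaluation

* **AUROC / AUPRC** via scikit-learn (Mann–Whitney with ties at 1/2;
  step-wise average precision). Both are cross-checked in the test suite
  against brute-force pair/threshold enumeration oracles on hundreds of
  random instances.
* **Confidence intervals**: percentile bootstrap (B = 1000 by default,
  pipeline default 300), resampling at the patient level so correlated
  fragments of one patient move together; degenerate single-class resamples
  are redrawn and counted.
* **Evaluation level**: metrics are reported both per fragment (each
  prediction an instance) and per patient (max risk within the 6 h horizon).
* **Thresholds** maximise sensitivity subject to specificity > 0.9 among
  midpoints of adjacent distinct validation scores (±∞ included); ties break
  toward the lower threshold (earlier alarms); thresholds are frozen before
  test data is touched. If only zero-sensitivity thresholds qualify, a +∞
  sentinel disables alarms with a warning.
* **Time to first alarm**: earliest fragment time with risk ≥ threshold
  within 360 min; otherwise censored and recorded as the sentinel 361 min
  ("> 6 h"). Earliness compares manual minus device alarm times per true
  positive: censored-manual pairs contribute a lower bound
  (360 − device time), censored-device pairs the mirrored upper bound,
  doubly censored pairs zero. Both the sum ("in total") and the per-patient
  minimum are reported.
* **Bland–Altman**: mean difference and mean ± 1.96 × SD (ddof = 1) of
  paired differences; pairs are device 5-min values vs coincident hourly
  manual readings pooled over patients.
* **Feature importance**: permutation importance, mean AUROC drop over
  column shuffles (seeded; default 10 repeats, pipeline default 5). For the
  accumulated model the permuted matrix is re-chunked into per-patient
  sequences before prediction so causality is preserved.
* **Label-permuted control**: patient-level label shuffling applied
  consistently to both sources, retraining from scratch. A single permutation
  at ~100 test patients can correlate with the signal by chance, so the
  control averages several independent permutations.

## Problem sizes and runtime

Default checks use cohorts of 60–500 patients. The end-to-end
discrimination/earliness checks use n = 400 at prevalence 0.16 with the
strong-signal configuration; unit-level recovery checks use records of
90–180 min. A 400-patient run (waveform synthesis, filtering, four model
fits, bootstrap with B = 100–200) takes 5–8 minutes on one CPU; waveforms
are processed streaming, one patient in memory at a time, and are not written
to disk by default.

## Known limitations

* The filtering rules' literal form has knife-edge cases (a single missing
  beat yields a unit at exactly 1.5× the median length; a single missing
  respiratory crest exactly halves the rate). The generator's artifacts avoid
  the knife edge by construction; real data would not always.
* Fragment-level discrimination is bounded by label broadcasting (see above);
  patient-level metrics are the cleaner summary of outcome discrimination.
* The earliness comparison inherits the alarm thresholds' variance: with few
  true positives in a test split, medians and sums are noisy.
* The accumulated model is a deliberately small LSTM; no architecture search
  was performed, and none of the default hyperparameters is tuned beyond
  "trains stably on the synthetic cohorts".
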