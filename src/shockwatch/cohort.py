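"""Synthetic febrile-patient cohort generator.

Emulates the monitoring setting the analysis assumes: adult emergency-department
patients with fever (>38 degC on arrival), continuous single-lead ECG (250 Hz) and
impedance-respiration (25 Hz) waveforms from a chest-worn device, hourly manual
vitals for up to 6 h, and a binary septic-shock outcome within 24 h of enrolment
(population prevalence ~16.2%). Shock patients deteriorate along a
piecewise-linear ramp (HR and RR rise, blood pressure falls, mental status dips)
beginning a configurable lead time before the shock event; non-shock patients
have stationary noisy vitals. Waveforms carry injectable artifacts (suppressed
beats, amplitude spikes, flatline dropouts) so that the downstream filtering
rules have something real to remove.

Every random draw flows from ``CohortConfig.seed`` through
``numpy.random.SeedSequence`` spawning, so a fixed seed reproduces the cohort
bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import stats
from scipy import signal as sp_signal

ECG_RATE_HZ = 250.0
RESP_RATE_HZ = 25.0
ADC_BITS = 14
ADC_FULL_SCALE = 5.0  # synthetic amplitude units mapped onto the 14-bit range

# physiologic clamps for ground-truth trajectories
HR_BOUNDS = (30.0, 220.0)
RR_BOUNDS = (5.0, 60.0)
SBP_BOUNDS = (50.0, 250.0)
DBP_BOUNDS = (30.0, 150.0)
GCS_BOUNDS = (3.0, 15.0)

#: deterioration reached at shock_time, relative to the patient's baseline
SHOCK_EFFECTS = {"hr": 40.0, "sbp": -35.0, "dbp": -20.0, "rr": 8.0, "gcs": -2.0}

#: modest shift of the presenting (baseline) vitals of eventual-shock patients;
#: emulates a sicker presentation without making the outcome trivially separable
SHOCK_BASELINE_SHIFT = {"hr": 8.0, "sbp": -8.0, "rr": 1.5}

#: AR(1) minute-scale noise on the true vitals
AR_PHI = 0.9
AR_INNOVATION_SD = {"hr": 2.0, "sbp": 3.0, "dbp": 2.0, "rr": 0.8, "gcs": 0.0}

#: observation noise of a manual (nurse-taken) reading
MANUAL_NOISE_SD = {"hr": 3.0, "sbp": 4.0, "dbp": 3.0, "rr": 1.5}


class ConfigError(ValueError):
    """A cohort configuration field is invalid."""


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 468
    shock_prevalence: float = 0.162
    monitoring_minutes_mean: float = 300.0
    monitoring_minutes_sd: float = 100.0
    monitoring_minutes_bounds: tuple[float, float] = (60.0, 360.0)
    artifact_rate: float = 0.05
    device_noise_sd_hr: float = 0.5  # bpm, beat-to-beat variability seen by the device
    device_noise_sd_rr: float = 0.5  # breaths/min, cycle-to-cycle variability
    lead_time_min: float = 180.0  # deterioration ramp length before shock_time
    shock_time_range_min: tuple[float, float] = (240.0, 480.0)
    effect_scale: float = 1.0  # multiplies SHOCK_EFFECTS (deterioration magnitude)
    baseline_shift_scale: float = 1.0  # multiplies SHOCK_BASELINE_SHIFT
    generate_waveforms: bool = True  # False: covariates/vitals only (fast, for statistics)
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 1:
            raise ConfigError(f"n_patients must be a positive integer, got {self.n_patients!r}")
        if not 0.0 <= self.shock_prevalence <= 1.0:
            raise ConfigError(f"shock_prevalence must be in [0, 1], got {self.shock_prevalence!r}")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ConfigError(f"artifact_rate must be in [0, 1), got {self.artifact_rate!r}")
        if self.monitoring_minutes_mean <= 0:
            raise ConfigError(
                f"monitoring_minutes_mean must be positive, got {self.monitoring_minutes_mean!r}"
            )
        if self.device_noise_sd_hr < 0:
            raise ConfigError(f"device_noise_sd_hr must be >= 0, got {self.device_noise_sd_hr!r}")
        if self.device_noise_sd_rr < 0:
            raise ConfigError(f"device_noise_sd_rr must be >= 0, got {self.device_noise_sd_rr!r}")
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")
        lo, hi = self.shock_time_range_min
        if not (0.0 < lo <= hi <= 1440.0):
            raise ConfigError(
                f"shock_time_range_min must lie within (0, 1440], got {self.shock_time_range_min!r}"
            )


@dataclass(frozen=True)
class ManualVitals:
    """One manually recorded set of vitals at ``t`` minutes from enrolment."""

    t: float
    sbp: float
    dbp: float
    hr: float
    rr: float
    mental_status: int  # Glasgow Coma Scale total, 3-15


@dataclass
class Waveform:
    """A single-channel waveform starting at ``t0`` minutes from enrolment.

    ``meta['peaks']`` holds the generator's ground-truth event positions
    (R-peaks for ECG, inspiratory crests for RESP); ``artifact_mask`` flags the
    samples a corruption touched. Both exist only so that recovery can be
    scored against truth — the filtering code never reads them.
    """

    channel: str  # "ECG" or "RESP"
    sampling_rate: float
    samples: np.ndarray
    t0: float = 0.0
    artifact_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channel not in ("ECG", "RESP"):
            raise ValueError(f"unknown channel {self.channel!r}")
        expected = {"ECG": ECG_RATE_HZ, "RESP": RESP_RATE_HZ}[self.channel]
        if self.sampling_rate != expected:
            raise ValueError(
                f"{self.channel} sampling_rate must be {expected} Hz, got {self.sampling_rate}"
            )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class GroundTruthTrajectory:
    """Per-minute true vitals from enrolment to monitoring end (generator only)."""

    minutes: np.ndarray
    hr: np.ndarray
    rr: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    gcs: np.ndarray

    def at_minute(self, vital: str, t_min: float) -> float:
        idx = min(int(t_min), len(self.minutes) - 1)
        return float(getattr(self, vital)[idx])


@dataclass
class PatientRecord:
    """One enrolled patient with covariates, vitals, waveforms and outcome."""

    patient_id: str
    age: float
    sex: int  # 0 female, 1 male
    bt_arrival: float  # degC, > 38.0 by inclusion criterion
    spo2_arrival: float
    manual_vitals: list[ManualVitals]
    ecg: Waveform | None  # None when generated with generate_waveforms=False
    resp: Waveform | None
    outcome: bool
    shock_time: float | None  # minutes from enrolment, present iff outcome
    duration_min: int = 0
    trajectory: GroundTruthTrajectory | None = None


# ---------------------------------------------------------------------------
# trajectories


def simulate_trajectory(
    baseline: Mapping[str, float],
    outcome: bool,
    shock_time: float | None,
    duration_min: int,
    rng: np.random.Generator | int,
    lead_min: float = 180.0,
    effects: Mapping[str, float] = SHOCK_EFFECTS,
) -> GroundTruthTrajectory:
    """Simulate per-minute true vitals.

    Non-shock patients get stationary AR(1) noise around their baseline. Shock
    patients additionally drift linearly from baseline toward
    ``baseline + effects`` over the ``lead_min`` minutes preceding
    ``shock_time`` (clamped to physiologic bounds). The ramp is what makes
    earliness of detection measurable downstream.
    """
    if outcome and shock_time is None:
        raise ValueError("shock_time is required when outcome is true")
    if not outcome and shock_time is not None:
        raise ValueError("shock_time must be absent when outcome is false")
    if shock_time is not None and not 0.0 < shock_time <= 1440.0:
        raise ValueError(f"shock_time must lie in (0, 1440] minutes, got {shock_time}")
    if duration_min < 1:
        raise ValueError("duration_min must be at least 1 minute")

    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    minutes = np.arange(duration_min, dtype=float)
    bounds = {"hr": HR_BOUNDS, "rr": RR_BOUNDS, "sbp": SBP_BOUNDS, "dbp": DBP_BOUNDS,
              "gcs": GCS_BOUNDS}
    series: dict[str, np.ndarray] = {}
    for vital in ("hr", "rr", "sbp", "dbp", "gcs"):
        drift = np.zeros(duration_min)
        if outcome:
            onset = shock_time - lead_min
            ramp = np.clip((minutes - onset) / lead_min, 0.0, 1.0)
            drift = ramp * effects.get(vital, 0.0)
        sd = AR_INNOVATION_SD[vital]
        noise = np.zeros(duration_min)
        if sd > 0:
            innov = rng.normal(0.0, sd, size=duration_min)
            innov[0] /= math.sqrt(1.0 - AR_PHI**2)  # stationary start
            noise = sp_signal.lfilter([1.0], [1.0, -AR_PHI], innov)
        lo, hi = bounds[vital]
        series[vital] = np.clip(baseline[vital] + drift + noise, lo, hi)
    return GroundTruthTrajectory(minutes=minutes, **series)


# ---------------------------------------------------------------------------
# waveform synthesis


def _quantize(x: np.ndarray) -> np.ndarray:
    """Emulate a 14-bit ADC over +/- ADC_FULL_SCALE amplitude units."""
    lsb = 2.0 * ADC_FULL_SCALE / 2**ADC_BITS
    return (np.round(x / lsb) * lsb).astype(np.float32)


def _qrs_template(fs: float, width_s: float = 0.015, amplitude: float = 1.0) -> np.ndarray:
    half = int(round(4 * width_s * fs))
    t = np.arange(-half, half + 1) / fs
    return (amplitude * np.exp(-0.5 * (t / width_s) ** 2)).astype(np.float32)


def synthesize_ecg(
    hr_per_minute: Sequence[float],
    rng: np.random.Generator | int,
    sampling_rate: float = ECG_RATE_HZ,
    interval_jitter_rel: float = 0.005,
    noise_sd: float = 0.04,
) -> Waveform:
    """Synthesize a single-lead ECG whose R-peak train tracks ``hr_per_minute``.

    The morphology is a Gaussian-bump QRS on a flat noisy baseline — enough for
    R-peak based heart-rate derivation, which is the only use the pipeline makes
    of the ECG. ``interval_jitter_rel`` is the relative SD of beat-to-beat
    interval variation (the device-side measurement noise).
    """
    hr = np.asarray(hr_per_minute, dtype=float)
    if hr.size == 0:
        raise ValueError("hr_per_minute must not be empty")
    if np.any((hr < HR_BOUNDS[0]) | (hr > HR_BOUNDS[1])):
        raise ValueError("hr_per_minute values must lie within [30, 220] bpm")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    duration_s = 60.0 * hr.size
    n = int(round(duration_s * sampling_rate))
    samples = rng.normal(0.0, noise_sd, size=n).astype(np.float32)

    # integrate the commanded instantaneous rate to place beats; jitter draws
    # are batched up front (one per possible beat) for speed
    max_beats = int(duration_s * HR_BOUNDS[1] / 60.0) + 2
    jitter = (np.exp(rng.normal(0.0, interval_jitter_rel, size=max_beats))
              if interval_jitter_rel > 0 else np.ones(max_beats))
    peak_times = []
    t = 0.3
    k = 0
    while t < duration_s - 0.1:
        peak_times.append(t)
        minute = min(int(t // 60.0), hr.size - 1)
        interval = (60.0 / hr[minute]) * jitter[k]
        k += 1
        t += max(interval, 0.25)
    peaks = np.asarray(np.round(np.array(peak_times) * sampling_rate), dtype=np.int64)
    peaks = peaks[peaks < n]

    template = _qrs_template(sampling_rate)
    half = len(template) // 2
    idx = peaks[:, None] + np.arange(-half, half + 1)[None, :]
    keep = (idx >= 0) & (idx < n)
    np.add.at(samples, idx[keep], np.broadcast_to(template, idx.shape)[keep])

    return Waveform(
        channel="ECG",
        sampling_rate=sampling_rate,
        samples=_quantize(samples),
        artifact_mask=np.zeros(n, dtype=bool),
        meta={"peaks": peaks},
    )


def synthesize_resp(
    rr_per_minute: Sequence[float],
    rng: np.random.Generator | int,
    sampling_rate: float = RESP_RATE_HZ,
    cycle_jitter_rel: float = 0.03,
    noise_sd: float = 0.05,
) -> Waveform:
    """Synthesize a quasi-sinusoidal impedance-respiration signal.

    Cycle crests occur at the commanded breathing rate with mild
    cycle-to-cycle phase jitter and slow amplitude modulation.
    """
    rr = np.asarray(rr_per_minute, dtype=float)
    if rr.size == 0:
        raise ValueError("rr_per_minute must not be empty")
    if np.any((rr < RR_BOUNDS[0]) | (rr > RR_BOUNDS[1])):
        raise ValueError("rr_per_minute values must lie within [5, 60] breaths/min")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    duration_s = 60.0 * rr.size
    n = int(round(duration_s * sampling_rate))
    t = np.arange(n) / sampling_rate
    minute = np.minimum((t // 60.0).astype(int), rr.size - 1)
    inst_rate_hz = rr[minute] / 60.0
    if cycle_jitter_rel > 0:
        # slow multiplicative jitter, resampled once per second
        per_sec = np.exp(rng.normal(0.0, cycle_jitter_rel, size=int(duration_s) + 1))
        inst_rate_hz = inst_rate_hz * per_sec[t.astype(int)]
    phase = 2.0 * np.pi * np.cumsum(inst_rate_hz) / sampling_rate
    amp = 1.0 + 0.1 * np.sin(2.0 * np.pi * t / 37.0)  # slow amplitude wander
    samples = (amp * np.sin(phase)).astype(np.float32)
    samples += rng.normal(0.0, noise_sd, size=n).astype(np.float32)

    # ground-truth crest positions: phase = pi/2 + 2*pi*k
    ks = np.arange(0, int((phase[-1] - np.pi / 2) // (2 * np.pi)) + 1)
    crest_phase = np.pi / 2 + 2 * np.pi * ks
    peaks = np.searchsorted(phase, crest_phase)
    peaks = peaks[peaks < n]

    return Waveform(
        channel="RESP",
        sampling_rate=sampling_rate,
        samples=_quantize(samples),
        artifact_mask=np.zeros(n, dtype=bool),
        meta={"peaks": peaks},
    )


def inject_artifacts(
    waveform: Waveform,
    artifact_rate: float,
    rng: np.random.Generator | int,
) -> Waveform:
    """Corrupt a random subset of beats/cycles, recording spans in the mask.

    Three corruption modes, chosen uniformly per corrupted unit: suppression of
    the event peak (the surrounding beat unit widens past the length rule),
    amplitude spikes (violating the amplitude rule), and flatline dropouts.
    ``artifact_rate == 0`` returns an untouched copy.
    """
    if not 0.0 <= artifact_rate < 1.0:
        raise ValueError(f"artifact_rate must be in [0, 1), got {artifact_rate}")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    samples = waveform.samples.copy()
    mask = np.zeros(len(samples), dtype=bool)
    peaks = np.asarray(waveform.meta.get("peaks", []), dtype=np.int64)
    corrupted: list[int] = []
    if artifact_rate > 0 and peaks.size:
        fs = waveform.sampling_rate
        hit = rng.random(peaks.size) < artifact_rate
        typical_max = float(np.percentile(np.abs(samples), 99.9)) or 1.0
        # corruption spans scale with the typical event interval so that
        # suppressions and dropouts swallow at least two beats/cycles
        med_int = float(np.median(np.diff(peaks))) if peaks.size > 1 else fs
        for i in np.flatnonzero(hit):
            p = int(peaks[i])
            # motion spikes are the most common patch artifact; suppressions
            # and contact dropouts each get half their frequency
            kind = int(rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25]))
            if kind == 0:  # suppress the peaks -> surrounding units widen
                w = int(1.1 * med_int)
                lo, hi = max(0, p - w), min(len(samples), p + w + 1)
                samples[lo:hi] = rng.normal(0.0, 0.02, size=hi - lo).astype(np.float32)
            elif kind == 1:  # amplitude spike
                w = max(2, int(0.02 * fs))
                lo, hi = max(0, p - w), min(len(samples), p + w + 1)
                samples[lo:hi] += np.float32(3.0 * typical_max)
            else:  # flatline dropout
                w = int(2.2 * med_int)
                lo, hi = p, min(len(samples), p + w)
                samples[lo:hi] = samples[lo] if lo < len(samples) else 0.0
            mask[lo:hi] = True
            corrupted.append(i)

    out = Waveform(
        channel=waveform.channel,
        sampling_rate=waveform.sampling_rate,
        samples=_quantize(samples) if corrupted else samples,
        t0=waveform.t0,
        artifact_mask=mask,
        meta=dict(waveform.meta, corrupted_units=corrupted),
    )
    return out


# ---------------------------------------------------------------------------
# whole-cohort generation


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float = np.inf) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_patient(config: CohortConfig, patient_id: str,
                  rng: np.random.Generator) -> PatientRecord:
    outcome = bool(rng.random() < config.shock_prevalence)
    shock_time = float(rng.uniform(*config.shock_time_range_min)) if outcome else None

    age = float(np.clip(rng.normal(57.0, 19.0), 18.0, 100.0))
    sex = int(rng.random() < 0.44)
    bt_arrival = _truncated_normal(rng, 38.64, 0.57, lo=38.001)
    spo2_arrival = float(np.clip(rng.normal(96.8, 2.5), 70.0, 100.0))
    duration_min = int(round(_truncated_normal(
        rng, config.monitoring_minutes_mean, config.monitoring_minutes_sd,
        *config.monitoring_minutes_bounds)))

    baseline = {
        "hr": float(np.clip(rng.normal(105.0, 12.0), 60.0, 150.0)),
        "rr": float(np.clip(rng.normal(18.2, 2.7), 10.0, 30.0)),
        "sbp": float(np.clip(rng.normal(127.0, 18.0), 80.0, 200.0)),
        "dbp": float(np.clip(rng.normal(76.0, 10.0), 45.0, 110.0)),
        "gcs": 15.0 if rng.random() < 0.95 else 14.0,
    }
    if outcome:
        for k, v in SHOCK_BASELINE_SHIFT.items():
            baseline[k] += v * config.baseline_shift_scale

    effects = {k: v * config.effect_scale for k, v in SHOCK_EFFECTS.items()}
    traj = simulate_trajectory(baseline, outcome, shock_time, duration_min, rng,
                               lead_min=config.lead_time_min, effects=effects)

    times = np.arange(0, duration_min + 1, 60)[: 7]
    times = times[times <= duration_min]
    manual = []
    for t in times:
        idx = min(int(t), duration_min - 1)
        manual.append(ManualVitals(
            t=float(t),
            sbp=float(traj.sbp[idx] + rng.normal(0, MANUAL_NOISE_SD["sbp"])),
            dbp=float(traj.dbp[idx] + rng.normal(0, MANUAL_NOISE_SD["dbp"])),
            hr=float(traj.hr[idx] + rng.normal(0, MANUAL_NOISE_SD["hr"])),
            rr=float(traj.rr[idx] + rng.normal(0, MANUAL_NOISE_SD["rr"])),
            mental_status=int(np.clip(round(traj.gcs[idx]), 3, 15)),
        ))

    ecg = resp = None
    if config.generate_waveforms:
        jitter_hr = config.device_noise_sd_hr / 100.0
        jitter_rr = config.device_noise_sd_rr / 18.0
        ecg = synthesize_ecg(traj.hr, rng, interval_jitter_rel=jitter_hr)
        resp = synthesize_resp(traj.rr, rng, cycle_jitter_rel=jitter_rr)
        if config.artifact_rate > 0:
            ecg = inject_artifacts(ecg, config.artifact_rate, rng)
            resp = inject_artifacts(resp, config.artifact_rate, rng)

    return PatientRecord(
        patient_id=patient_id,
        age=age,
        sex=sex,
        bt_arrival=bt_arrival,
        spo2_arrival=spo2_arrival,
        manual_vitals=manual,
        ecg=ecg,
        resp=resp,
        outcome=outcome,
        shock_time=shock_time,
        duration_min=duration_min,
        trajectory=traj,
    )


def strong_signal_config(n_patients: int = 400, seed: int = 0,
                         shock_prevalence: float = 0.16) -> CohortConfig:
    """A cohort whose deterioration is unambiguous at the fragment level.

    Septic deterioration begins soon after arrival (shock at 180-300 min, so
    the ramp starts within the first 2 h of monitoring) and reaches 1.75x the
    default effect sizes. Used for end-to-end discrimination and earliness
    sanity checks, where the question is whether the pipeline finds a signal
    that is — by construction — clearly there.
    """
    return CohortConfig(n_patients=n_patients, shock_prevalence=shock_prevalence,
                        shock_time_range_min=(180.0, 300.0), effect_scale=1.75,
                        seed=seed)


def iter_cohort(config: CohortConfig) -> Iterator[PatientRecord]:
    """Yield patients one at a time (waveforms are large; stream when possible)."""
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    for i, ss in enumerate(seeds):
        yield _draw_patient(config, patient_id=f"P{i:04d}", rng=np.random.default_rng(ss))


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Materialise the full cohort. Reproducible bit-for-bit for a fixed seed."""
    return list(iter_cohort(config))
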