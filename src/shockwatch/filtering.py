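"""Waveform filtering: beat units, exclusion rules, and 1 Hz vital series.

The ECG is sliced into beat units centred on each detected R-peak (unit
boundaries at the midpoints between neighbouring peaks, edge units extended to
the record ends, so the units tile the record). A unit is excluded when

* its length exceeds 1.5x the median unit length, or
* its maximum amplitude exceeds 2x the median of per-unit maxima, or
* its minimum amplitude undercuts 2x the median of per-unit minima
  (i.e. twice as deep, for a signal riding on a near-zero baseline);

all medians are computed once over the entire record before any flag is set.
Each unit carries the heart rate of its beat (60 / R-R interval in seconds),
and excluded units are bridged by carry-forward imputation on a 1 Hz grid.

Respiration is handled after the ECG: samples overlapping ECG-excluded spans
are discarded first, cycle crests are detected, per-cycle rate is 60 / crest
interval, and a cycle is excluded when its rate falls below 0.5x or rises
above 1.5x the previous *valid* rate (comparing against an excluded value
would propagate artifacts). Carry-forward fills excluded cycles on the same
1 Hz grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy.ndimage import uniform_filter1d

from .cohort import ECG_RATE_HZ, RESP_RATE_HZ, Waveform

LENGTH_RULE_FACTOR = 1.5
AMPLITUDE_RULE_FACTOR = 2.0
RESP_LOW_FACTOR = 0.5
RESP_HIGH_FACTOR = 1.5
REFRACTORY_S = 0.2


@dataclass(slots=True)
class EcgUnit:
    """One QRS-centred beat slice, half-open on ``[start_idx, end_idx)``."""

    start_idx: int
    end_idx: int
    r_peak_idx: int
    unit_max: float
    unit_min: float
    hr_value: float  # bpm, 60 / R-R interval of this beat
    valid: bool = True
    rules_violated: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return self.end_idx - self.start_idx


@dataclass(slots=True)
class RespCycle:
    """One breath: the interval between consecutive detected crests."""

    peak_idx: int
    next_peak_idx: int
    cycle_interval: float  # seconds
    rr_value: float  # breaths/min, 60 / cycle_interval
    valid: bool = True
    rules_violated: tuple[str, ...] = ()


@dataclass
class VitalSeries:
    """A gap-free 1 Hz vital-sign series with carry-forward provenance."""

    t: np.ndarray  # seconds, exact 1 s grid from 0
    value: np.ndarray
    imputed: np.ndarray  # True where carry-forward (or backfill) supplied the value
    name: str = ""

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.value) == len(self.imputed)):
            raise ValueError("t, value and imputed must have equal length")
        if np.any(np.isnan(self.value)):
            raise ValueError("VitalSeries must be gap-free after imputation")


# ---------------------------------------------------------------------------
# R-peak detection


def _otsu_threshold(values: np.ndarray, bins: int = 128) -> float:
    """Otsu's between-class-variance maximising threshold on a 1-D sample."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        return lo
    hist, edges = np.histogram(values, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cw = np.cumsum(w)
    cm = np.cumsum(w * centers)
    mean_total = cm[-1] / total
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mean_total * cw - cm) ** 2 / (cw * (total - cw))
    between[~np.isfinite(between)] = -1.0
    return float(centers[int(np.argmax(between))])


def detect_r_peaks(ecg: Waveform, refractory_s: float = REFRACTORY_S) -> np.ndarray:
    """Detect R-peak sample indices in a 250 Hz single-lead ECG.

    Band-pass (5-30 Hz) energy with an adaptive threshold: a first pass finds
    candidate peaks, the threshold is re-set to a fraction of their median
    energy (robust to spike artifacts), and accepted peaks are refined to the
    local raw-signal maximum. A refractory period of ``refractory_s`` is
    enforced throughout.
    """
    if ecg.channel != "ECG":
        raise ValueError(f"expected an ECG waveform, got channel {ecg.channel!r}")
    fs = ecg.sampling_rate
    x = np.asarray(ecg.samples, dtype=np.float32)  # single precision suffices here
    if len(x) < 2 * fs:
        raise ValueError("ECG record shorter than 2 s cannot be processed")
    if np.std(x) == 0:
        warnings.warn("zero-variance ECG signal; no QRS complexes detected")
        return np.array([], dtype=np.int64)

    sos = sp_signal.butter(3, [5.0, 30.0], btype="bandpass", fs=fs,
                           output="sos").astype(np.float32)
    filt = sp_signal.sosfiltfilt(sos, x)
    energy = uniform_filter1d(filt * filt, size=max(3, int(0.10 * fs)))

    dist = max(1, int(refractory_s * fs))
    cand, _ = sp_signal.find_peaks(energy, distance=dist)
    if cand.size == 0:
        return np.array([], dtype=np.int64)
    # candidate energies are bimodal (noise maxima vs QRS); split them with an
    # Otsu threshold on the log scale, then re-detect at that height so the
    # refractory distance is enforced among accepted peaks only
    level = _otsu_threshold(np.log10(energy[cand] + 1e-12))
    peaks, _ = sp_signal.find_peaks(energy, height=10.0**level, distance=dist)

    # refine to the local maximum of a lightly smoothed raw signal within
    # +/- 40 ms (smoothing suppresses sample-level noise on the flat QRS apex)
    w = int(0.04 * fs)
    smooth = uniform_filter1d(x, size=5)
    pad = np.pad(smooth, w, constant_values=-np.inf)
    windows = pad[peaks[:, None] + np.arange(2 * w + 1)[None, :]]
    refined = peaks + windows.argmax(axis=1) - w
    refined = np.clip(refined, 0, len(x) - 1)
    refined = np.unique(refined)
    # discard edge peaks born from the zero-phase filter's boundary transient
    edge = int(0.1 * fs)
    refined = refined[(refined >= edge) & (refined < len(x) - edge)]
    if refined.size:
        keep = [int(refined[0])]
        for p in refined[1:]:
            if p - keep[-1] >= dist:
                keep.append(int(p))
        refined = np.asarray(keep, dtype=np.int64)
    return refined


# ---------------------------------------------------------------------------
# unit slicing and the exclusion rules


def slice_units(ecg: Waveform, peaks: np.ndarray) -> list[EcgUnit]:
    """Slice the record into QRS-centred units that tile it without overlap.

    Unit *i* spans midpoint(peak_{i-1}, peak_i) to midpoint(peak_i, peak_{i+1});
    the first and last units extend to the record edges. The per-unit heart
    rate is 60 over the beat's preceding R-R interval (the first unit uses the
    following interval, the only one it has).
    """
    peaks = np.asarray(peaks, dtype=np.int64)
    if peaks.size < 3:
        raise ValueError(f"need at least 3 R-peaks to slice units, got {peaks.size}")
    n = len(ecg.samples)
    fs = ecg.sampling_rate
    mids = (peaks[:-1] + peaks[1:]) // 2
    starts = np.concatenate(([0], mids))
    ends = np.concatenate((mids, [n]))

    x = np.asarray(ecg.samples, dtype=np.float64)
    maxs = np.maximum.reduceat(x, starts)
    mins = np.minimum.reduceat(x, starts)

    rr_prev = np.diff(peaks) / fs  # interval ending at peak i+1
    hr = np.empty(peaks.size)
    hr[1:] = 60.0 / rr_prev
    hr[0] = 60.0 / rr_prev[0]

    return [
        EcgUnit(start_idx=int(s), end_idx=int(e), r_peak_idx=int(p),
                unit_max=float(mx), unit_min=float(mn), hr_value=float(h))
        for s, e, p, mx, mn, h in zip(starts, ends, peaks, maxs, mins, hr)
    ]


def filter_ecg_units(units: list[EcgUnit]) -> list[EcgUnit]:
    """Apply the three exclusion rules, flagging ``valid`` in place.

    Medians of length, per-unit maximum and per-unit minimum are computed once
    over all units of the record; a unit fails when its length exceeds 1.5x
    the median length, its maximum exceeds 2x the median maximum, or its
    minimum lies below 2x the median minimum.
    """
    if len(units) < 3:
        raise ValueError("need at least 3 units to apply the exclusion rules")
    lengths = np.array([u.length for u in units], dtype=float)
    maxs = np.array([u.unit_max for u in units])
    mins = np.array([u.unit_min for u in units])
    med_len = float(np.median(lengths))
    med_max = float(np.median(maxs))
    med_min = float(np.median(mins))

    for u in units:
        rules = []
        if u.length > LENGTH_RULE_FACTOR * med_len:
            rules.append("length")
        if u.unit_max > AMPLITUDE_RULE_FACTOR * med_max:
            rules.append("max_amplitude")
        if u.unit_min < AMPLITUDE_RULE_FACTOR * med_min:
            rules.append("min_amplitude")
        u.rules_violated = tuple(rules)
        u.valid = not rules
    return units


def excluded_spans_s(units: list[EcgUnit], fs: float = ECG_RATE_HZ) -> list[tuple[float, float]]:
    """Time spans (seconds) covered by excluded units, for the respiration pass."""
    return [(u.start_idx / fs, u.end_idx / fs) for u in units if not u.valid]


# ---------------------------------------------------------------------------
# 1 Hz series with carry-forward


def _carry_forward(values: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill invalid entries with the most recent valid value; backfill the head."""
    if not valid.any():
        raise ValueError("no valid values to carry forward: record unusable")
    idx = np.where(valid, np.arange(len(values)), -1)
    idx = np.maximum.accumulate(idx)
    first_valid = int(np.argmax(valid))
    idx[idx < 0] = first_valid  # leading invalid span backfilled
    return values[idx], ~valid


def compute_hr_series(
    units: list[EcgUnit],
    duration_s: int,
    fs: float = ECG_RATE_HZ,
) -> VitalSeries:
    """Per-second heart rate from filtered beat units.

    The value at second ``t`` is the ``hr_value`` of the unit containing the
    second's first sample; seconds covered by excluded units take the most
    recent valid value (carry-forward), flagged in the ``imputed`` mask.
    """
    if not units:
        raise ValueError("no units supplied")
    starts = np.array([u.start_idx for u in units])
    hr = np.array([u.hr_value for u in units])
    ok = np.array([u.valid for u in units])
    if not ok.any():
        raise ValueError("all units excluded: record unusable")

    sec_samples = (np.arange(duration_s) * fs).astype(np.int64)
    unit_of_sec = np.searchsorted(starts, sec_samples, side="right") - 1
    unit_of_sec = np.clip(unit_of_sec, 0, len(units) - 1)
    values, imputed = _carry_forward(hr[unit_of_sec], ok[unit_of_sec])
    return VitalSeries(t=np.arange(duration_s, dtype=float), value=values,
                       imputed=imputed, name="hr")


def detect_resp_peaks(
    resp: Waveform,
    min_separation_s: float = 1.0,
    prominence: float = 0.3,
) -> np.ndarray:
    """Respiratory crest indices: local maxima with a minimum prominence and a
    1 s minimum separation (60 breaths/min ceiling)."""
    if resp.channel != "RESP":
        raise ValueError(f"expected a RESP waveform, got channel {resp.channel!r}")
    x = np.asarray(resp.samples, dtype=np.float64)
    # light smoothing sharpens crest localisation against sample noise
    x = uniform_filter1d(x, size=max(3, int(0.4 * resp.sampling_rate)))
    dist = max(1, int(min_separation_s * resp.sampling_rate))
    peaks, _ = sp_signal.find_peaks(x, distance=dist, prominence=prominence)
    return peaks.astype(np.int64)


def compute_rr_series(
    resp: Waveform,
    excluded_ecg_spans: list[tuple[float, float]],
    duration_s: int,
    min_separation_s: float = 1.0,
    prominence: float = 0.3,
) -> tuple[VitalSeries, list[RespCycle]]:
    """Per-second respiratory rate from crest intervals.

    ECG-excluded time spans are removed first: crests inside them are dropped
    and cycles overlapping them are marked invalid. Remaining cycles obey the
    0.5x / 1.5x rule against the previous valid rate. Invalid cycles (and
    seconds before the first / after the last crest) are carry-forward filled.
    """
    fs = resp.sampling_rate
    peaks = detect_resp_peaks(resp, min_separation_s, prominence)

    bad_sample = np.zeros(len(resp.samples), dtype=bool)
    for lo_s, hi_s in excluded_ecg_spans:
        lo = max(0, int(np.floor(lo_s * fs)))
        hi = min(len(bad_sample), int(np.ceil(hi_s * fs)))
        bad_sample[lo:hi] = True
    peaks = peaks[~bad_sample[peaks]]
    if peaks.size < 2:
        raise ValueError("no respiratory cycles detected: record unusable")

    # The 0.5x/1.5x rule compares against the previous *valid* rate. A wrongly
    # accepted half-rate cycle (e.g. from a missed crest) would otherwise lock
    # the chain: every true cycle then looks >1.5x and is excluded forever. A
    # bounded reset re-anchors the chain on the next plausible cycle after
    # ``reset_after`` consecutive rate-rule exclusions.
    reset_after = 5
    cycles: list[RespCycle] = []
    prev_valid_rr: float | None = None
    consecutive_rate_excl = 0
    for p, q in zip(peaks[:-1], peaks[1:]):
        interval = (q - p) / fs
        rr = 60.0 / interval
        rules = []
        if bad_sample[p:q].any():
            rules.append("ecg_excluded_overlap")
        plausible = 5.0 <= rr <= 60.0
        if not plausible:
            rules.append("implausible_rate")
        if prev_valid_rr is not None and consecutive_rate_excl < reset_after:
            if rr < RESP_LOW_FACTOR * prev_valid_rr:
                rules.append("rate_low")
            elif rr > RESP_HIGH_FACTOR * prev_valid_rr:
                rules.append("rate_high")
        cyc = RespCycle(peak_idx=int(p), next_peak_idx=int(q), cycle_interval=interval,
                        rr_value=rr, valid=not rules, rules_violated=tuple(rules))
        cycles.append(cyc)
        if cyc.valid:
            prev_valid_rr = rr
            consecutive_rate_excl = 0
        elif "rate_low" in rules or "rate_high" in rules:
            consecutive_rate_excl += 1

    starts = np.array([c.peak_idx for c in cycles])
    rr_vals = np.array([c.rr_value for c in cycles])
    ok = np.array([c.valid for c in cycles])
    if not ok.any():
        raise ValueError("all respiratory cycles excluded: record unusable")

    sec_samples = (np.arange(duration_s) * fs).astype(np.int64)
    cyc_of_sec = np.searchsorted(starts, sec_samples, side="right") - 1
    covered = (cyc_of_sec >= 0) & (sec_samples < cycles[-1].next_peak_idx)
    cyc_of_sec = np.clip(cyc_of_sec, 0, len(cycles) - 1)
    values, imputed = _carry_forward(rr_vals[cyc_of_sec], ok[cyc_of_sec] & covered)
    series = VitalSeries(t=np.arange(duration_s, dtype=float), value=values,
                         imputed=imputed, name="rr")
    return series, cycles


# ---------------------------------------------------------------------------
# per-patient convenience


@dataclass
class FilterResult:
    hr: VitalSeries
    rr: VitalSeries
    units: list[EcgUnit] = field(repr=False, default_factory=list)
    cycles: list[RespCycle] = field(repr=False, default_factory=list)


def filter_patient(ecg: Waveform, resp: Waveform, duration_s: int | None = None) -> FilterResult:
    """Run the full filtering chain for one patient's two waveforms."""
    if duration_s is None:
        duration_s = int(min(ecg.duration_s, resp.duration_s))
    peaks = detect_r_peaks(ecg)
    units = filter_ecg_units(slice_units(ecg, peaks))
    hr = compute_hr_series(units, duration_s, fs=ecg.sampling_rate)
    rr, cycles = compute_rr_series(resp, excluded_spans_s(units, ecg.sampling_rate), duration_s)
    return FilterResult(hr=hr, rr=rr, units=units, cycles=cycles)
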