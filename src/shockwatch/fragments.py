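"""Assembly of 14-value feature fragments.

A fragment is the model's unit of input at one timestamp: four static values
recorded on arrival (age, sex, body temperature, oxygen saturation), five
dynamic vitals (SBP, DBP, HR, RR, mental status as the GCS total), and the
five differences of the dynamic vitals against their baseline values.

Manual fragments are built from the hourly nurse readings (t = 0, 60, ...
minutes, up to 6 h or the end of monitoring). Device fragments are built every
5 minutes, with HR and RR replaced by the filtered 1 Hz device series
(windowed median over the trailing 5 minutes); blood pressure and mental
status, which the device does not measure, are carried forward from the most
recent manual reading. Device HR/RR deltas are taken against the t = 0 device
values, the remaining deltas against the manual baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import PatientRecord
from .filtering import VitalSeries

#: canonical feature order of the 14-column design matrix
FEATURE_ORDER: tuple[str, ...] = (
    "age", "sex", "bt_arrival", "spo2_arrival",
    "sbp", "dbp", "hr", "rr", "gcs",
    "d_sbp", "d_dbp", "d_hr", "d_rr", "d_gcs",
)

STATIC_FIELDS = FEATURE_ORDER[:4]
DYNAMIC_FIELDS = FEATURE_ORDER[4:9]
DELTA_FIELDS = FEATURE_ORDER[9:]

MANUAL_SPACING_MIN = 60.0
DEVICE_SPACING_MIN = 5.0


@dataclass(frozen=True)
class Fragment:
    """One 14-value feature vector at ``t`` minutes from enrolment."""

    t: float
    source: str  # "manual" or "device"
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = [k for k in FEATURE_ORDER if k not in self.values]
        if missing:
            raise ValueError(f"fragment at t={self.t} missing fields: {missing}")

    def as_row(self, feature_order: tuple[str, ...] = FEATURE_ORDER) -> np.ndarray:
        return np.array([self.values[k] for k in feature_order], dtype=float)


@dataclass
class FragmentSequence:
    """All fragments of one patient from one source, with the outcome label."""

    patient_id: str
    source: str
    fragments: list[Fragment]
    label: bool
    label_time: float | None = None  # shock_time, minutes

    def __post_init__(self) -> None:
        ts = [f.t for f in self.fragments]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("fragments must be strictly increasing in t")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.fragments])

    def truncated(self, t_max: float) -> "FragmentSequence":
        """Fragments with t <= t_max (used for causality checks and alarms)."""
        return FragmentSequence(
            patient_id=self.patient_id, source=self.source,
            fragments=[f for f in self.fragments if f.t <= t_max],
            label=self.label, label_time=self.label_time,
        )


def _static_block(patient: PatientRecord) -> dict[str, float]:
    return {
        "age": float(patient.age),
        "sex": float(patient.sex),
        "bt_arrival": float(patient.bt_arrival),
        "spo2_arrival": float(patient.spo2_arrival),
    }


def build_manual_fragments(patient: PatientRecord) -> FragmentSequence:
    """One fragment per hourly manual reading; deltas against the t=0 reading."""
    if not patient.manual_vitals:
        raise ValueError(f"patient {patient.patient_id} has no manual vitals")
    baseline = patient.manual_vitals[0]
    if baseline.t != 0.0:
        raise ValueError(
            f"patient {patient.patient_id} is missing the baseline (t=0) reading"
        )
    static = _static_block(patient)
    frags = []
    for mv in patient.manual_vitals:
        dyn = {"sbp": mv.sbp, "dbp": mv.dbp, "hr": mv.hr, "rr": mv.rr,
               "gcs": float(mv.mental_status)}
        base = {"sbp": baseline.sbp, "dbp": baseline.dbp, "hr": baseline.hr,
                "rr": baseline.rr, "gcs": float(baseline.mental_status)}
        values = dict(static)
        values.update(dyn)
        values.update({f"d_{k}": dyn[k] - base[k] for k in base})
        frags.append(Fragment(t=float(mv.t), source="manual", values=values))
    return FragmentSequence(patient_id=patient.patient_id, source="manual",
                            fragments=frags, label=patient.outcome,
                            label_time=patient.shock_time)


def _window_median(series: VitalSeries, t_min: float, spacing_min: float) -> float:
    """Median of the 1 Hz values in the trailing window (t-spacing, t] minutes."""
    if t_min == 0.0:
        return float(series.value[0])
    hi = int(round(t_min * 60.0))
    lo = max(0, int(round((t_min - spacing_min) * 60.0)) + 1)
    hi = min(hi, len(series.value) - 1)
    return float(np.median(series.value[lo:hi + 1]))


def build_device_fragments(
    patient: PatientRecord,
    hr_series: VitalSeries,
    rr_series: VitalSeries,
    spacing_min: float = DEVICE_SPACING_MIN,
) -> FragmentSequence:
    """Fragments on the 5-minute device grid.

    HR and RR come from the filtered device series (trailing-window median);
    SBP, DBP and GCS are carried forward from the most recent manual reading.
    HR/RR deltas use the t=0 device values as baseline, the carried manual
    values keep the manual baseline.
    """
    if len(hr_series.value) < spacing_min * 60 or len(rr_series.value) < spacing_min * 60:
        raise ValueError("device series shorter than one 5-minute window")
    if not patient.manual_vitals or patient.manual_vitals[0].t != 0.0:
        raise ValueError(
            f"patient {patient.patient_id} is missing the baseline (t=0) reading"
        )
    baseline = patient.manual_vitals[0]
    static = _static_block(patient)

    duration_min = min(len(hr_series.value), len(rr_series.value)) / 60.0
    n_steps = int(np.floor(duration_min / spacing_min + 1e-9))
    grid = np.arange(n_steps + 1) * spacing_min  # floor(duration/5) + 1 fragments

    hr0 = _window_median(hr_series, 0.0, spacing_min)
    rr0 = _window_median(rr_series, 0.0, spacing_min)

    manual_ts = [mv.t for mv in patient.manual_vitals]
    frags = []
    for t in grid:
        mi = int(np.searchsorted(manual_ts, t, side="right")) - 1
        mv = patient.manual_vitals[max(mi, 0)]
        hr_t = _window_median(hr_series, float(t), spacing_min)
        rr_t = _window_median(rr_series, float(t), spacing_min)
        values = dict(static)
        values.update({"sbp": mv.sbp, "dbp": mv.dbp, "hr": hr_t, "rr": rr_t,
                       "gcs": float(mv.mental_status)})
        values.update({
            "d_sbp": mv.sbp - baseline.sbp,
            "d_dbp": mv.dbp - baseline.dbp,
            "d_hr": hr_t - hr0,
            "d_rr": rr_t - rr0,
            "d_gcs": float(mv.mental_status - baseline.mental_status),
        })
        frags.append(Fragment(t=float(t), source="device", values=values))
    return FragmentSequence(patient_id=patient.patient_id, source="device",
                            fragments=frags, label=patient.outcome,
                            label_time=patient.shock_time)


def fragments_to_matrix(
    seq: FragmentSequence,
    feature_order: tuple[str, ...] = FEATURE_ORDER,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Stack a sequence into an (n_fragments, 14) matrix.

    Returns ``(X, t, label)``; column order follows ``feature_order`` and is
    bit-stable across runs. Raises if any fragment misses a value.
    """
    if sorted(feature_order) != sorted(FEATURE_ORDER):
        raise ValueError("feature_order must be a permutation of the 14 canonical names")
    rows, ts = [], []
    for f in seq.fragments:
        for k in feature_order:
            v = f.values.get(k)
            if v is None or not np.isfinite(v):
                raise ValueError(f"missing or non-finite value {k!r} at t={f.t}")
        rows.append(f.as_row(feature_order))
        ts.append(f.t)
    return np.asarray(rows, dtype=float), np.asarray(ts, dtype=float), seq.label


def matrix_to_fragments(
    X: np.ndarray,
    t: np.ndarray,
    label: bool,
    patient_id: str,
    source: str,
    feature_order: tuple[str, ...] = FEATURE_ORDER,
) -> FragmentSequence:
    """Inverse of :func:`fragments_to_matrix` (round-trip identity)."""
    frags = [
        Fragment(t=float(ti), source=source,
                 values={k: float(v) for k, v in zip(feature_order, row)})
        for ti, row in zip(t, X)
    ]
    return FragmentSequence(patient_id=patient_id, source=source,
                            fragments=frags, label=label)
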