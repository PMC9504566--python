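"""File contracts: plain CSV artifacts with JSON sidecars.

Every artifact written by one pipeline stage is readable by the next without
manual edits; readers validate schemas and name the offending file/column on
violation. Waveforms are stored as flat one-column CSVs next to a JSON
sidecar carrying channel, sampling rate, t0 and length.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ECG_RATE_HZ, RESP_RATE_HZ, ManualVitals, PatientRecord, Waveform
from .filtering import VitalSeries
from .fragments import FEATURE_ORDER, Fragment, FragmentSequence

MANIFEST_COLUMNS = ["patient_id", "age", "sex", "bt_arrival", "spo2_arrival",
                    "outcome", "shock_time", "duration_min"]
VITALS_COLUMNS = ["patient_id", "t_min", "sbp", "dbp", "hr", "rr", "gcs"]
FRAGMENT_COLUMNS = ["patient_id", "t_min", "source", *FEATURE_ORDER, "label"]
PREDICTION_COLUMNS = ["patient_id", "t_min", "risk", "source", "model_kind", "split", "label"]
SERIES_COLUMNS = ["patient_id", "t_s", "hr", "hr_imputed", "rr", "rr_imputed"]


class SchemaError(ValueError):
    """An artifact does not match its file contract."""


def _require_columns(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


# --- cohort manifest -------------------------------------------------------

def write_manifest(patients: list[PatientRecord], path: Path) -> None:
    rows = [{
        "patient_id": p.patient_id, "age": p.age, "sex": p.sex,
        "bt_arrival": p.bt_arrival, "spo2_arrival": p.spo2_arrival,
        "outcome": int(p.outcome),
        "shock_time": p.shock_time if p.shock_time is not None else "",
        "duration_min": p.duration_min,
    } for p in patients]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, MANIFEST_COLUMNS, Path(path))
    return df


# --- manual vitals ---------------------------------------------------------

def write_manual_vitals(patients: list[PatientRecord], path: Path) -> None:
    rows = [{
        "patient_id": p.patient_id, "t_min": mv.t, "sbp": mv.sbp, "dbp": mv.dbp,
        "hr": mv.hr, "rr": mv.rr, "gcs": mv.mental_status,
    } for p in patients for mv in p.manual_vitals]
    pd.DataFrame(rows, columns=VITALS_COLUMNS).to_csv(path, index=False)


def read_manual_vitals(path: Path) -> dict[str, list[ManualVitals]]:
    df = pd.read_csv(path)
    _require_columns(df, VITALS_COLUMNS, Path(path))
    out: dict[str, list[ManualVitals]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.patient_id, []).append(ManualVitals(
            t=float(row.t_min), sbp=float(row.sbp), dbp=float(row.dbp),
            hr=float(row.hr), rr=float(row.rr), mental_status=int(row.gcs)))
    return out


# --- waveforms -------------------------------------------------------------

def write_waveform(wf: Waveform, path: Path) -> None:
    """Flat sample CSV plus a JSON sidecar ``<path>.json``."""
    path = Path(path)
    np.savetxt(path, wf.samples, fmt="%.6g")
    sidecar = {"channel": wf.channel, "sampling_rate": wf.sampling_rate,
               "t0": wf.t0, "length": int(len(wf.samples))}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_waveform(path: Path) -> Waveform:
    path = Path(path)
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise SchemaError(f"{path}: missing JSON sidecar")
    meta = json.loads(sidecar_path.read_text())
    for key in ("channel", "sampling_rate", "t0", "length"):
        if key not in meta:
            raise SchemaError(f"{sidecar_path}: sidecar missing {key!r}")
    expected = {"ECG": ECG_RATE_HZ, "RESP": RESP_RATE_HZ}.get(meta["channel"])
    if expected is None or meta["sampling_rate"] != expected:
        raise SchemaError(
            f"{sidecar_path}: channel {meta['channel']!r} requires sampling_rate "
            f"{expected}, got {meta['sampling_rate']}")
    samples = np.loadtxt(path, dtype=np.float32, ndmin=1)
    if len(samples) != meta["length"]:
        raise SchemaError(
            f"{path}: sample count {len(samples)} != sidecar length {meta['length']}")
    return Waveform(channel=meta["channel"], sampling_rate=meta["sampling_rate"],
                    samples=samples, t0=meta["t0"])


# --- 1 Hz vital series -----------------------------------------------------

def write_vital_series(patient_id: str, hr: VitalSeries, rr: VitalSeries,
                       path: Path) -> None:
    n = min(len(hr.value), len(rr.value))
    pd.DataFrame({
        "patient_id": patient_id, "t_s": hr.t[:n].astype(int),
        "hr": hr.value[:n], "hr_imputed": hr.imputed[:n].astype(int),
        "rr": rr.value[:n], "rr_imputed": rr.imputed[:n].astype(int),
    }).to_csv(path, index=False)


def read_vital_series(path: Path) -> tuple[str, VitalSeries, VitalSeries]:
    df = pd.read_csv(path)
    _require_columns(df, SERIES_COLUMNS, Path(path))
    pid = str(df["patient_id"].iloc[0])
    t = df["t_s"].to_numpy(dtype=float)
    hr = VitalSeries(t=t, value=df["hr"].to_numpy(float),
                     imputed=df["hr_imputed"].to_numpy(bool), name="hr")
    rr = VitalSeries(t=t, value=df["rr"].to_numpy(float),
                     imputed=df["rr_imputed"].to_numpy(bool), name="rr")
    return pid, hr, rr


# --- fragments -------------------------------------------------------------

def write_fragments(seqs: list[FragmentSequence], path: Path) -> None:
    rows = []
    for seq in seqs:
        for f in seq.fragments:
            row = {"patient_id": seq.patient_id, "t_min": f.t, "source": f.source,
                   "label": int(seq.label)}
            row.update({k: f.values[k] for k in FEATURE_ORDER})
            rows.append(row)
    pd.DataFrame(rows, columns=FRAGMENT_COLUMNS).to_csv(path, index=False)


def read_fragments(path: Path) -> list[FragmentSequence]:
    df = pd.read_csv(path)
    _require_columns(df, FRAGMENT_COLUMNS, Path(path))
    seqs = []
    for (pid, source), grp in df.groupby(["patient_id", "source"], sort=True):
        grp = grp.sort_values("t_min")
        frags = [
            Fragment(t=float(r.t_min), source=str(source),
                     values={k: float(getattr(r, k)) for k in FEATURE_ORDER})
            for r in grp.itertuples(index=False)
        ]
        seqs.append(FragmentSequence(patient_id=str(pid), source=str(source),
                                     fragments=frags,
                                     label=bool(grp["label"].iloc[0])))
    return seqs


# --- predictions and reports ----------------------------------------------

def write_predictions(rows: list[dict], path: Path) -> None:
    pd.DataFrame(rows, columns=PREDICTION_COLUMNS).to_csv(path, index=False)


def read_predictions(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PREDICTION_COLUMNS, Path(path))
    return df


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: Path):
    return json.loads(Path(path).read_text())
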