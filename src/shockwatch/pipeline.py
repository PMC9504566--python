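"""End-to-end run: simulate -> filter -> fragment -> train -> evaluate.

A :class:`RunConfig` fully determines a run; the global seed fans out through
``numpy.random.SeedSequence`` to the cohort, the split, each model fit and the
bootstrap, so rerunning the same config reproduces the report byte-for-byte.
Waveforms are processed streaming (one patient in memory at a time) and are
not persisted by default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as swio
from .cohort import CohortConfig, iter_cohort
from .filtering import filter_patient
from .fragments import (FEATURE_ORDER, FragmentSequence, build_device_fragments,
                        build_manual_fragments, fragments_to_matrix)
from .models import ModelConfig, TrainedModel, predict_risk_trajectory, split_cohort, train_model
from .evaluation import (bland_altman, evaluate_run, permutation_importance)

log = logging.getLogger(__name__)

SOURCES = ("manual", "device")
KINDS = ("fragmented", "accumulated")


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one full pipeline run."""

    seed: int
    out_dir: str
    cohort: CohortConfig = field(default_factory=CohortConfig)
    encoder_widths: tuple[int, ...] = (16, 8)
    hidden_size: int = 12
    learning_rate: float = 0.03
    max_epochs: int = 200
    patience: int = 25
    bootstrap_B: int = 300
    min_specificity: float = 0.9
    horizon_min: float = 360.0
    importance_repeats: int = 5
    write_vital_series: bool = False

    def __post_init__(self) -> None:
        if self.seed is None or not isinstance(self.seed, int):
            raise ValueError("RunConfig.seed is mandatory and must be an integer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "seed" not in d:
            raise ValueError("config is missing the mandatory 'seed' field")
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            for key in ("monitoring_minutes_bounds", "shock_time_range_min"):
                if key in cohort and isinstance(cohort[key], list):
                    cohort[key] = tuple(cohort[key])
            cohort = CohortConfig(**dict(cohort, seed=cohort.get("seed", d["seed"])))
        if isinstance(d.get("encoder_widths"), list):
            d["encoder_widths"] = tuple(d["encoder_widths"])
        return cls(cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % 2**31)
            for c in np.random.SeedSequence(seed).spawn(n)]


def build_patient_fragments(config: RunConfig):
    """Stream the cohort through filtering and fragment assembly.

    Returns (patients_meta, sequences, agreement_pairs, excluded_ids).
    ``sequences`` maps source -> list of FragmentSequence. Patients whose
    records are unusable after filtering are excluded (with a log line), the
    same way technically failed recordings drop out of a device study.
    """
    cohort_seed = _child_seeds(config.seed, 4)[0]
    cohort_cfg = dataclasses.replace(config.cohort, seed=cohort_seed)

    sequences: dict[str, list[FragmentSequence]] = {"manual": [], "device": []}
    patients_meta = []
    excluded = []
    ba_pairs = {"hr": [], "rr": []}
    vital_rows = []

    for patient in iter_cohort(cohort_cfg):
        try:
            res = filter_patient(patient.ecg, patient.resp)
            manual_seq = build_manual_fragments(patient)
            device_seq = build_device_fragments(patient, res.hr, res.rr)
        except (ValueError, RuntimeError) as exc:
            log.warning("excluding %s: %s", patient.patient_id, exc)
            excluded.append(patient.patient_id)
            continue
        sequences["manual"].append(manual_seq)
        sequences["device"].append(device_seq)
        patients_meta.append(patient)

        device_by_t = {f.t: f for f in device_seq.fragments}
        for mv, frag in ((mv, device_by_t.get(mv.t)) for mv in patient.manual_vitals):
            if frag is not None:
                ba_pairs["hr"].append((frag.values["hr"], mv.hr))
                ba_pairs["rr"].append((frag.values["rr"], mv.rr))

        if config.write_vital_series:
            vital_rows.append((patient.patient_id, res.hr, res.rr))

        patient.ecg = None  # free waveform memory; downstream uses fragments only
        patient.resp = None
    return patients_meta, sequences, ba_pairs, excluded, vital_rows


def _collect_predictions(model: TrainedModel, seqs: list[FragmentSequence]):
    scores, labels, groups, rows = [], [], [], []
    risk_by_patient, label_by_patient = {}, {}
    for seq in seqs:
        traj = predict_risk_trajectory(model, seq)
        scores.append(traj.risk)
        labels.append(np.full(len(traj.risk), float(seq.label)))
        groups.append(np.repeat(seq.patient_id, len(traj.risk)))
        risk_by_patient[seq.patient_id] = (traj.t, traj.risk)
        label_by_patient[seq.patient_id] = seq.label
        rows += [{"patient_id": seq.patient_id, "t_min": float(t), "risk": float(r),
                  "source": seq.source, "model_kind": model.kind}
                 for t, r in zip(traj.t, traj.risk)]
    return (np.concatenate(scores), np.concatenate(labels), np.concatenate(groups),
            risk_by_patient, label_by_patient, rows)


def _sequence_predict_fn(model: TrainedModel, seqs: list[FragmentSequence]):
    """Fragment-matrix predict function for permutation importance.

    For the accumulated model the permuted matrix is re-chunked into the
    original per-patient sequences before prediction, preserving causality.
    """
    lengths = [len(s.fragments) for s in seqs]
    bounds = np.cumsum([0, *lengths])

    def predict(X: np.ndarray) -> np.ndarray:
        if model.kind in ("fragmented", "logistic_baseline"):
            return model.predict_fragments(X, model.feature_order)
        out = []
        for i in range(len(seqs)):
            Z = model._transform(X[bounds[i]:bounds[i + 1]])[None, :, :]
            mask = np.ones((1, lengths[i]), dtype=bool)
            out.append(model.net.predict(Z, mask)[0])
        return np.concatenate(out)

    return predict


def fit_models_and_predict(
    sequences: dict[str, list[FragmentSequence]],
    split: dict[str, str],
    config: RunConfig,
    model_seed: int,
):
    """Train the four model x source combinations and score valid/test sets.

    Returns (predictions, prediction_rows, models, train_log); ``predictions``
    is keyed by (model_kind, source) in the layout ``evaluate_run`` expects.
    """
    by_split = {s: {src: [q for q in sequences[src] if split[q.patient_id] == s]
                    for src in SOURCES}
                for s in ("train", "validation", "test")}

    predictions = {}
    prediction_rows: list[dict] = []
    models: dict[tuple[str, str], TrainedModel] = {}
    train_log: list[dict] = []
    for k, kind in enumerate(KINDS):
        for s, source in enumerate(SOURCES):
            mcfg = ModelConfig(
                model_kind=kind, encoder_widths=config.encoder_widths,
                hidden_size=config.hidden_size, learning_rate=config.learning_rate,
                max_epochs=config.max_epochs, patience=config.patience,
                seed=model_seed + 10 * k + s,
            )
            model = train_model(by_split["train"][source],
                                by_split["validation"][source], mcfg)
            models[(kind, source)] = model
            vs, vl, vg, _, vlbp, vrows = _collect_predictions(
                model, by_split["validation"][source])
            ts, tl, tg, rbp, lbp, trows = _collect_predictions(
                model, by_split["test"][source])
            for row in vrows:
                row["split"] = "validation"
                row["label"] = int(vlbp[row["patient_id"]])
            for row in trows:
                row["split"] = "test"
                row["label"] = int(lbp[row["patient_id"]])
            prediction_rows += vrows + trows
            predictions[(kind, source)] = {
                "valid_scores": vs, "valid_labels": vl, "valid_groups": vg,
                "scores": ts, "labels": tl, "groups": tg,
                "risk_by_patient": rbp, "label_by_patient": lbp,
            }
            train_log.append({
                "model": kind, "source": source, "epochs": len(model.history),
                "best_val_auroc": max((h["val_auroc"] for h in model.history),
                                      default=None),
            })
    return predictions, prediction_rows, models, train_log


def permute_labels(sequences: dict[str, list[FragmentSequence]],
                   seed: int) -> dict[str, list[FragmentSequence]]:
    """Patient-level label permutation (the negative control for learning).

    Labels are shuffled once across patients and applied consistently to the
    manual and device sequence of each patient; features stay untouched.
    """
    ids = sorted({s.patient_id for seqs in sequences.values() for s in seqs})
    labels = {pid: None for pid in ids}
    for seqs in sequences.values():
        for s in seqs:
            labels[s.patient_id] = s.label
    perm = np.random.default_rng(seed).permutation(len(ids))
    new_label = {pid: labels[ids[j]] for pid, j in zip(ids, perm)}
    out: dict[str, list[FragmentSequence]] = {}
    for src, seqs in sequences.items():
        out[src] = [FragmentSequence(patient_id=s.patient_id, source=s.source,
                                     fragments=s.fragments,
                                     label=new_label[s.patient_id],
                                     label_time=None)
                    for s in seqs]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 4)
    stage_log: list[dict] = []

    def _log_stage(name: str, **info) -> None:
        stage_log.append({"stage": name, **info})
        log.info("stage %s: %s", name, info)

    patients, sequences, ba_pairs, excluded, vital_rows = build_patient_fragments(config)
    _log_stage("simulate_filter_fragment", n_patients=len(patients),
               n_excluded=len(excluded))
    if len(patients) < 5:
        raise RuntimeError("stage simulate: fewer than 5 usable patients")

    swio.write_manifest(patients, out / "manifest.csv")
    swio.write_manual_vitals(patients, out / "manual_vitals.csv")
    swio.write_fragments(sequences["manual"] + sequences["device"],
                         out / "fragments.csv")
    for pid, hr, rr in vital_rows:
        swio.write_vital_series(pid, hr, rr, out / f"vitals_{pid}.csv")

    ids = [p.patient_id for p in patients]
    split = split_cohort(ids, seeds[1])
    swio.write_json(split, out / "split.json")
    _log_stage("split", sizes={s: list(split.values()).count(s)
                               for s in ("train", "validation", "test")})

    predictions, prediction_rows, models, train_log = fit_models_and_predict(
        sequences, split, config, seeds[2])
    for entry in train_log:
        _log_stage("train", **entry)
    swio.write_predictions(prediction_rows, out / "predictions.csv")

    results = evaluate_run(predictions, bootstrap_B=config.bootstrap_B,
                           seed=seeds[3], min_specificity=config.min_specificity,
                           horizon=config.horizon_min)
    _log_stage("evaluate", n_reports=len(results["reports"]))

    importance = {}
    test_seqs = {src: [q for q in sequences[src] if split[q.patient_id] == "test"]
                 for src in SOURCES}
    for combo in models:
        seqs = test_seqs[combo[1]]
        X = np.concatenate([fragments_to_matrix(s)[0] for s in seqs])
        y = np.concatenate([np.full(len(s.fragments), float(s.label)) for s in seqs])
        importance["_".join(combo)] = permutation_importance(
            models[combo], X, y, FEATURE_ORDER, seed=seeds[3],
            n_repeats=config.importance_repeats,
            predict=_sequence_predict_fn(models[combo], seqs))
    _log_stage("importance", combos=sorted(importance))

    agreement = {name: bland_altman([a for a, _ in pairs], [b for _, b in pairs])
                 for name, pairs in ba_pairs.items() if len(pairs) >= 3}

    report = {
        "config_hash": config.config_hash(),
        "seeds": seeds,
        "n_patients": len(patients),
        "n_excluded": len(excluded),
        "prevalence": float(np.mean([p.outcome for p in patients])),
        "split_sizes": {s: list(split.values()).count(s)
                        for s in ("train", "validation", "test")},
        "metrics": [r.as_dict() for r in results["reports"]],
        "earliness": {
            kind: {
                "total_delta_min": res.total_delta_min,
                "min_delta_min": res.min_delta_min,
                "median_device_alarm_min": _median_alarm(
                    results["alarms"][(kind, "device")], results["true_positive_ids"]),
                "median_manual_alarm_min": _median_alarm(
                    results["alarms"][(kind, "manual")], results["true_positive_ids"]),
                "n_device_alarmed": res.n_device_alarmed,
                "n_manual_alarmed": res.n_manual_alarmed,
                "n_true_positives": len(results["true_positive_ids"]),
            } for kind, res in results["earliness"].items()
        },
        "agreement": {name: dataclasses.asdict(a) for name, a in agreement.items()},
        "feature_importance": importance,
    }
    swio.write_json(report, out / "report.json")

    alarm_rows = [{"model_kind": kind, "source": source, "patient_id": a.patient_id,
                   "first_alarm_t": a.first_alarm_t, "censored": int(a.censored)}
                  for (kind, source), recs in results["alarms"].items() for a in recs]
    swio.write_json(alarm_rows, out / "alarms.json")
    swio.write_json({"config": config.to_dict(), "stages": stage_log},
                    out / "run_log.json")

    return {"report": report, "results": results, "models": models,
            "predictions": predictions, "split": split, "out_dir": str(out),
            "sequences": sequences, "agreement": agreement}


def _median_alarm(alarms, tp_ids) -> float:
    ts = [a.first_alarm_t for a in alarms if a.patient_id in tp_ids]
    return float(np.median(ts)) if ts else float("nan")
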