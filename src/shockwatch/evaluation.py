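"""Discrimination, agreement, earliness and importance metrics.

Covers the full evaluation the analysis needs:

* AUROC (Mann-Whitney pairwise probability, ties at 1/2) and AUPRC (step-wise
  average precision) with patient-level percentile-bootstrap 95% CIs;
* threshold selection at maximum sensitivity subject to specificity above a
  floor (0.9 by default), chosen on validation scores and frozen for test;
* censored time-to-first-alarm within a 6 h acquisition horizon, and the
  device-vs-manual earliness comparison over true positives;
* Bland-Altman limits of agreement (mean difference +/- 1.96 SD of the paired
  differences) for device-vs-manual measurement comparison;
* permutation feature importance (mean AUROC drop over column shuffles).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

log = logging.getLogger(__name__)

DEFAULT_HORIZON_MIN = 360.0
DEFAULT_MIN_SPECIFICITY = 0.9


# ---------------------------------------------------------------------------
# threshold-free discrimination


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(float)
    if set(np.unique(labels)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    return labels


def compute_auroc(scores, labels) -> float:
    """Area under the ROC curve; equals P(score_pos > score_neg) + P(tie)/2."""
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def compute_auprc(scores, labels) -> float:
    """Area under the precision-recall curve, by the step-wise (average
    precision) convention: sum over recall increments of the precision at each
    threshold. Equals the prevalence when all scores tie."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def bootstrap_ci(
    metric,
    scores,
    labels,
    B: int = 1000,
    seed: int = 0,
    groups=None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric(scores, labels)``.

    Resampling is at the patient level when ``groups`` is given (all rows of a
    resampled patient enter together), otherwise at the row level. Degenerate
    resamples (a single class) are redrawn; the redraw count is logged.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for a stable percentile interval")
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    rng = np.random.default_rng(seed)

    if groups is None:
        group_ids = np.arange(len(scores))
        index_of = {g: np.array([g]) for g in group_ids}
    else:
        groups = np.asarray(groups)
        group_ids = np.unique(groups)
        index_of = {g: np.flatnonzero(groups == g) for g in group_ids}

    stats = np.empty(B)
    redraws = 0
    for b in range(B):
        while True:
            take = rng.choice(group_ids, size=len(group_ids), replace=True)
            idx = np.concatenate([index_of[g] for g in take])
            if labels[idx].min() != labels[idx].max():
                break
            redraws += 1
            if redraws > 50 * B:
                raise RuntimeError("bootstrap cannot find two-class resamples")
        stats[b] = metric(scores[idx], labels[idx])
    if redraws:
        log.info("bootstrap redrew %d degenerate resamples", redraws)
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# threshold selection and alarms


def sens_spec_at(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    """Sensitivity and specificity of the rule score >= threshold."""
    pred = scores >= threshold
    pos = labels > 0
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[~pos]).mean()) if (~pos).any() else float("nan")
    return sens, spec


def select_threshold(
    scores_valid,
    labels_valid,
    min_specificity: float = DEFAULT_MIN_SPECIFICITY,
) -> float:
    """Maximum-sensitivity threshold with specificity above ``min_specificity``.

    Candidates are midpoints between adjacent distinct scores plus one below
    the minimum and one above the maximum; ties in sensitivity resolve to the
    lowest qualifying threshold (earliest alarms). Returns +inf with a warning
    when no candidate attains the specificity floor.
    """
    scores = np.asarray(scores_valid, dtype=float)
    labels = _check_binary(labels_valid)
    if labels.min() == labels.max():
        raise ValueError("threshold selection needs both classes present")
    uniq = np.unique(scores)
    candidates = np.concatenate((
        [uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]))
    best_t, best_sens = np.inf, 0.0
    for t in candidates:
        sens, spec = sens_spec_at(scores, labels, t)
        if spec > min_specificity and (
            sens > best_sens or (sens == best_sens and t < best_t)
        ):
            best_t, best_sens = float(t), sens
    if not np.isfinite(best_t) or best_sens == 0.0:
        # only sensitivity-zero thresholds qualify: no alarms are possible
        warnings.warn(
            f"no useful threshold reaches specificity > {min_specificity}; "
            "alarms disabled"
        )
        return np.inf
    return best_t


@dataclass(frozen=True)
class AlarmRecord:
    """Earliest alarm of one patient under a fixed threshold.

    Censored patients (no crossing within the horizon) record the sentinel
    ``horizon + 1`` so the value reads as "> 6 h".
    """

    patient_id: str
    first_alarm_t: float  # minutes; horizon + 1 when censored
    censored: bool


def time_to_first_alarm(traj, threshold: float,
                        horizon: float = DEFAULT_HORIZON_MIN) -> AlarmRecord:
    """Earliest fragment time with risk >= threshold, censored past ``horizon``."""
    t = np.asarray(traj.t, dtype=float)
    risk = np.asarray(traj.risk, dtype=float)
    if t.size == 0:
        raise ValueError("empty risk trajectory")
    hit = (risk >= threshold) & (t <= horizon)
    if hit.any():
        return AlarmRecord(traj.patient_id, float(t[np.argmax(hit)]), censored=False)
    return AlarmRecord(traj.patient_id, horizon + 1.0, censored=True)


@dataclass
class EarlinessResult:
    """Device-vs-manual alarm timing over the same true-positive patients.

    ``delta`` per patient is manual minus device alarm time (positive when the
    device alarms earlier). When the manual alarm is censored but the device
    alarmed, only a lower bound (horizon - device time) is known; the converse
    gives an upper bound; doubly censored pairs contribute zero.
    """

    per_patient: list[dict] = field(default_factory=list)
    total_delta_min: float = 0.0  # sum of deltas / bounds ("in total")
    min_delta_min: float = 0.0  # smallest per-patient delta ("at the minimum")
    n_device_alarmed: int = 0
    n_manual_alarmed: int = 0


def earliness_comparison(
    alarms_device: list[AlarmRecord],
    alarms_manual: list[AlarmRecord],
    true_positive_ids: set[str] | None = None,
    horizon: float = DEFAULT_HORIZON_MIN,
) -> EarlinessResult:
    """Compare alarm times for the patients both sources cover."""
    dev = {a.patient_id: a for a in alarms_device}
    man = {a.patient_id: a for a in alarms_manual}
    if set(dev) != set(man):
        raise ValueError(
            f"alarm sets cover different patients: {sorted(set(dev) ^ set(man))[:5]}"
        )
    ids = sorted(dev) if true_positive_ids is None else sorted(
        set(dev) & set(true_positive_ids))

    result = EarlinessResult()
    deltas = []
    for pid in ids:
        a_d, a_m = dev[pid], man[pid]
        if not a_d.censored and not a_m.censored:
            delta, bound = a_m.first_alarm_t - a_d.first_alarm_t, "exact"
        elif a_m.censored and not a_d.censored:
            delta, bound = horizon - a_d.first_alarm_t, "lower"
        elif a_d.censored and not a_m.censored:
            delta, bound = a_m.first_alarm_t - horizon, "upper"
        else:
            delta, bound = 0.0, "both_censored"
        deltas.append(delta)
        result.per_patient.append({
            "patient_id": pid, "device_t": a_d.first_alarm_t,
            "manual_t": a_m.first_alarm_t, "delta_min": delta, "bound": bound,
        })
    result.total_delta_min = float(np.sum(deltas)) if deltas else 0.0
    result.min_delta_min = float(np.min(deltas)) if deltas else 0.0
    result.n_device_alarmed = sum(not dev[p].censored for p in ids)
    result.n_manual_alarmed = sum(not man[p].censored for p in ids)
    return result


# ---------------------------------------------------------------------------
# device agreement


@dataclass(frozen=True)
class AgreementResult:
    mean_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


def bland_altman(values_a, values_b) -> AgreementResult:
    """Bland-Altman agreement: mean difference and 95% limits of agreement
    (mean +/- 1.96 x sample SD of the differences, ddof=1)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    diffs = a - b
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(mean_diff=mean, loa_low=mean - 1.96 * sd,
                           loa_high=mean + 1.96 * sd, n_pairs=a.size)


# ---------------------------------------------------------------------------
# feature importance


def permutation_importance(
    model,
    X: np.ndarray,
    labels: np.ndarray,
    feature_names: tuple[str, ...],
    seed: int = 0,
    n_repeats: int = 10,
    predict=None,
) -> list[tuple[str, float]]:
    """Mean AUROC drop when one feature column is shuffled, ranked descending.

    ``predict`` defaults to ``model.predict_fragments``; pass a callable for
    sequence models (it receives the permuted matrix).
    """
    if X.shape[1] < 2:
        raise ValueError("permutation importance needs at least 2 features")
    predict = predict or (lambda M: model.predict_fragments(M, feature_names))
    labels = _check_binary(labels)
    rng = np.random.default_rng(seed)
    base = compute_auroc(predict(X), labels)
    scores = []
    for j, name in enumerate(feature_names):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            drops.append(base - compute_auroc(predict(Xp), labels))
        scores.append((name, float(np.mean(drops))))
    return sorted(scores, key=lambda kv: -kv[1])


# ---------------------------------------------------------------------------
# run-level report


@dataclass
class MetricReport:
    """One model x data-source row of the performance table."""

    model_kind: str
    source: str
    level: str  # "fragment" or "patient"
    threshold: float
    auroc: float
    auroc_ci: tuple[float, float]
    auprc: float
    auprc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "model_kind": self.model_kind, "source": self.source,
            "level": self.level, "threshold": self.threshold,
            "auroc": self.auroc, "auroc_ci": list(self.auroc_ci),
            "auprc": self.auprc, "auprc_ci": list(self.auprc_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
        }


REQUIRED_COMBINATIONS = (
    ("fragmented", "manual"), ("fragmented", "device"),
    ("accumulated", "manual"), ("accumulated", "device"),
)


def _patient_level(pred: dict, horizon: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Max risk within the horizon per patient, with patient labels."""
    ids = sorted(pred["risk_by_patient"])
    scores, labels = [], []
    for pid in ids:
        t, r = pred["risk_by_patient"][pid]
        within = np.asarray(t) <= horizon
        scores.append(float(np.max(np.asarray(r)[within])) if within.any() else 0.0)
        labels.append(float(pred["label_by_patient"][pid]))
    return np.asarray(scores), np.asarray(labels), np.asarray(ids)


def evaluate_run(
    predictions: dict[tuple[str, str], dict],
    bootstrap_B: int = 1000,
    seed: int = 0,
    min_specificity: float = DEFAULT_MIN_SPECIFICITY,
    horizon: float = DEFAULT_HORIZON_MIN,
) -> dict:
    """Build the four-row performance report plus alarms and earliness.

    ``predictions`` maps (model_kind, source) to a dict with keys
    ``valid_scores``, ``valid_labels``, ``valid_groups`` (validation-fragment
    arrays), ``scores``, ``labels``, ``groups`` (test-fragment arrays) and
    ``risk_by_patient`` / ``label_by_patient`` (test patients; per-patient
    ``(t, risk)`` pairs and labels). Thresholds are selected on the validation
    scores only and frozen before touching the test data.
    """
    missing = [c for c in REQUIRED_COMBINATIONS if c not in predictions]
    if missing:
        raise ValueError(f"missing model x data combinations: {missing}")

    reports: list[MetricReport] = []
    alarms: dict[tuple[str, str], list[AlarmRecord]] = {}
    for combo in REQUIRED_COMBINATIONS:
        pred = predictions[combo]
        threshold = select_threshold(pred["valid_scores"], pred["valid_labels"],
                                     min_specificity)
        for level in ("fragment", "patient"):
            if level == "fragment":
                scores = np.asarray(pred["scores"], dtype=float)
                labels = _check_binary(pred["labels"])
                groups = np.asarray(pred["groups"])
            else:
                scores, labels, groups = _patient_level(pred, horizon)
            sens, spec = sens_spec_at(scores, labels, threshold)
            reports.append(MetricReport(
                model_kind=combo[0], source=combo[1], level=level,
                threshold=threshold,
                auroc=compute_auroc(scores, labels),
                auroc_ci=bootstrap_ci(compute_auroc, scores, labels,
                                      B=bootstrap_B, seed=seed, groups=groups),
                auprc=compute_auprc(scores, labels),
                auprc_ci=bootstrap_ci(compute_auprc, scores, labels,
                                      B=bootstrap_B, seed=seed, groups=groups),
                sensitivity=sens,
                sensitivity_ci=bootstrap_ci(
                    lambda s, l, t=threshold: sens_spec_at(s, l, t)[0],
                    scores, labels, B=bootstrap_B, seed=seed, groups=groups),
                specificity=spec,
                specificity_ci=bootstrap_ci(
                    lambda s, l, t=threshold: sens_spec_at(s, l, t)[1],
                    scores, labels, B=bootstrap_B, seed=seed, groups=groups),
            ))
        alarms[combo] = [
            time_to_first_alarm(
                RiskLike(pid, *pred["risk_by_patient"][pid]), threshold, horizon)
            for pid in sorted(pred["risk_by_patient"])
        ]

    tp_ids = {
        pid for pid, lab in predictions[REQUIRED_COMBINATIONS[0]]["label_by_patient"].items()
        if lab
    }
    earliness = {
        kind: earliness_comparison(
            alarms[(kind, "device")], alarms[(kind, "manual")], tp_ids, horizon)
        for kind in ("fragmented", "accumulated")
    }
    return {"reports": reports, "alarms": alarms, "earliness": earliness,
            "true_positive_ids": tp_ids}


@dataclass
class RiskLike:
    """Duck-typed stand-in for a RiskTrajectory built from stored arrays."""

    patient_id: str
    t: np.ndarray
    risk: np.ndarray
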