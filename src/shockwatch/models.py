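"""Outcome predictors: fragmented, accumulated, and a logistic baseline.

Two model structures share one contract — map fragments to a septic-shock
risk in [0, 1] at each fragment time:

* the *fragmented* model scores each 14-value fragment independently (a small
  dense network);
* the *accumulated* model scores the whole fragment history up to each time
  point (the same kind of encoder feeding a single-layer LSTM), so its risk at
  time t uses only fragments with t' <= t;
* ``logistic_baseline`` is a scikit-learn logistic regression on single
  fragments, useful as a fully deterministic reference.

Training minimises class-weighted binary cross-entropy with early stopping on
validation AUROC. Every fragment of a shock patient carries the patient-level
positive label (the outcome is defined per patient within 24 h; no
time-varying labels are available). Features are z-scored with training-set
statistics only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ._nets import MLP, Adam, LSTMNet, bce_with_logits
from .fragments import FEATURE_ORDER, FragmentSequence, fragments_to_matrix

MODEL_KINDS = ("fragmented", "accumulated", "logistic_baseline")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters; none are dictated by the problem, all live here."""

    model_kind: str = "fragmented"
    encoder_widths: tuple[int, ...] = (16, 8)
    hidden_size: int = 12  # LSTM memory (accumulated kind only)
    learning_rate: float = 0.03
    max_epochs: int = 200
    patience: int = 25
    scale: bool = True
    class_weighted: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}, got {self.model_kind!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(w < 1 for w in self.encoder_widths) or self.hidden_size < 1:
            raise ValueError("layer sizes must be positive")
        if self.max_epochs < 1 or self.patience < 1 or self.learning_rate <= 0:
            raise ValueError("training schedule values must be positive")


@dataclass
class RiskTrajectory:
    """Per-fragment risk of septic shock for one patient."""

    patient_id: str
    t: np.ndarray  # minutes, matching the fragment grid
    risk: np.ndarray  # probabilities in [0, 1]
    source: str = ""
    model_kind: str = ""


def split_cohort(patient_ids: Sequence[str], seed: int) -> dict[str, str]:
    """Random patient-level 6:2:2 split.

    Validation and test each get floor(0.2 n); the remainder trains. The
    assignment is a deterministic function of the seed.
    """
    ids = list(patient_ids)
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 patients to split 6:2:2, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = n_test = n // 5
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_val:
            assignment[ids[idx]] = "validation"
        elif rank < n_val + n_test:
            assignment[ids[idx]] = "test"
        else:
            assignment[ids[idx]] = "train"
    return assignment


def _stack_fragments(seqs: Iterable[FragmentSequence],
                     feature_order: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    X, y = [], []
    for seq in seqs:
        Xi, _, label = fragments_to_matrix(seq, feature_order)
        X.append(Xi)
        y.append(np.full(len(Xi), float(label)))
    return np.concatenate(X), np.concatenate(y)


def _pad_sequences(seqs: Sequence[FragmentSequence],
                   feature_order: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mats = [fragments_to_matrix(s, feature_order)[0] for s in seqs]
    y = np.array([float(s.label) for s in seqs])
    T = max(len(m) for m in mats)
    B, F = len(mats), len(feature_order)
    X = np.zeros((B, T, F))
    mask = np.zeros((B, T), dtype=bool)
    for i, m in enumerate(mats):
        X[i, :len(m)] = m
        mask[i, :len(m)] = True
    return X, y, mask


def _class_weights(y: np.ndarray, enabled: bool) -> np.ndarray:
    if not enabled:
        return np.ones_like(y)
    n, n_pos = len(y), y.sum()
    if n_pos == 0 or n_pos == n:
        raise ValueError("training labels contain a single class")
    w = np.where(y > 0, n / (2.0 * n_pos), n / (2.0 * (n - n_pos)))
    return w


class TrainedModel:
    """A fitted predictor with its scaler and feature order frozen in."""

    def __init__(self, kind: str, net, mean: np.ndarray, sd: np.ndarray,
                 feature_order: tuple[str, ...], config: ModelConfig,
                 history: list[dict] | None = None):
        self.kind = kind
        self.net = net
        self.mean = mean
        self.sd = sd
        self.feature_order = feature_order
        self.config = config
        self.history = history or []

    def _transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def predict_fragments(self, X: np.ndarray,
                          feature_order: tuple[str, ...] = FEATURE_ORDER) -> np.ndarray:
        """Per-row risks for a (n, 14) fragment matrix (fragmented/logistic only)."""
        if feature_order != self.feature_order:
            raise ValueError("feature order does not match the training order")
        Z = self._transform(X)
        if self.kind == "logistic_baseline":
            return self.net.predict_proba(Z)[:, 1]
        if self.kind == "fragmented":
            return self.net.predict(Z)
        raise ValueError("accumulated models need a sequence; use predict_sequence")

    def predict_sequence(self, seq: FragmentSequence) -> np.ndarray:
        X, _, _ = fragments_to_matrix(seq, self.feature_order)
        if self.kind in ("fragmented", "logistic_baseline"):
            return self.predict_fragments(X, self.feature_order)
        Z = self._transform(X)[None, :, :]
        mask = np.ones((1, len(X)), dtype=bool)
        return self.net.predict(Z, mask)[0]


def train_model(
    train_seqs: Sequence[FragmentSequence],
    valid_seqs: Sequence[FragmentSequence],
    config: ModelConfig,
    feature_order: tuple[str, ...] = FEATURE_ORDER,
) -> TrainedModel:
    """Fit one model kind on training sequences with early stopping.

    Raises if training labels are single-class, if train and validation share
    patients, or if the loss goes non-finite.
    """
    overlap = {s.patient_id for s in train_seqs} & {s.patient_id for s in valid_seqs}
    if overlap:
        raise ValueError(f"patients present in both train and validation: {sorted(overlap)[:5]}")

    Xtr, ytr = _stack_fragments(train_seqs, feature_order)
    if ytr.min() == ytr.max():
        raise ValueError("training labels contain a single class")
    if config.scale:
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
    else:
        mean = np.zeros(Xtr.shape[1])
        sd = np.ones(Xtr.shape[1])

    if config.model_kind == "logistic_baseline":
        clf = LogisticRegression(max_iter=2000, random_state=config.seed)
        w = _class_weights(ytr, config.class_weighted)
        clf.fit((Xtr - mean) / sd, ytr, sample_weight=w)
        return TrainedModel("logistic_baseline", clf, mean, sd, feature_order, config)

    rng = np.random.default_rng(config.seed)
    history: list[dict] = []

    if config.model_kind == "fragmented":
        net = MLP((len(feature_order), *config.encoder_widths, 1), rng)
        Ztr = (Xtr - mean) / sd
        wtr = _class_weights(ytr, config.class_weighted)
        Xva, yva = _stack_fragments(valid_seqs, feature_order)
        Zva = (Xva - mean) / sd

        opt = Adam(net.params, lr=config.learning_rate)
        best_auc, best_params, best_epoch = -np.inf, None, -1
        for epoch in range(config.max_epochs):
            logits, cache = net.forward(Ztr)
            loss, dlogits = bce_with_logits(logits, ytr, wtr)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {loss}")
            opt.step(net.backward(cache, dlogits))
            val_auc = roc_auc_score(yva, net.predict(Zva)) if yva.min() != yva.max() else 0.5
            history.append({"epoch": epoch, "loss": loss, "val_auroc": float(val_auc)})
            if val_auc > best_auc:
                best_auc, best_epoch = val_auc, epoch
                best_params = copy.deepcopy(net.params)
            elif epoch - best_epoch >= config.patience:
                break
        if best_params is not None:
            net.params.update(best_params)
        return TrainedModel("fragmented", net, mean, sd, feature_order, config, history)

    # accumulated
    net = LSTMNet(len(feature_order), config.encoder_widths[0], config.hidden_size, rng)
    Xp, yp, mask = _pad_sequences(train_seqs, feature_order)
    Zp = (Xp - mean) / sd * mask[..., None]
    ystep = np.broadcast_to(yp[:, None], mask.shape).copy()
    wstep = np.broadcast_to(_class_weights(yp, config.class_weighted)[:, None], mask.shape) * mask

    Xv, yv, mv = _pad_sequences(valid_seqs, feature_order)
    Zv = (Xv - mean) / sd * mv[..., None]
    yv_flat = np.broadcast_to(yv[:, None], mv.shape)[mv]

    opt = Adam(net.params, lr=config.learning_rate)
    best_auc, best_params, best_epoch = -np.inf, None, -1
    for epoch in range(config.max_epochs):
        logits, cache = net.forward(Zp, mask)
        loss, dlogits = bce_with_logits(logits, ystep, wstep)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at epoch {epoch}: {loss}")
        opt.step(net.backward(cache, dlogits))
        pv = net.predict(Zv, mv)[mv]
        val_auc = roc_auc_score(yv_flat, pv) if yv_flat.min() != yv_flat.max() else 0.5
        history.append({"epoch": epoch, "loss": loss, "val_auroc": float(val_auc)})
        if val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_params = copy.deepcopy(net.params)
        elif epoch - best_epoch >= config.patience:
            break
    if best_params is not None:
        net.params.update(best_params)
    return TrainedModel("accumulated", net, mean, sd, feature_order, config, history)


def predict_risk_trajectory(model: TrainedModel, seq: FragmentSequence) -> RiskTrajectory:
    """One risk per fragment time; causal for the accumulated kind."""
    risks = model.predict_sequence(seq)
    return RiskTrajectory(patient_id=seq.patient_id, t=seq.times, risk=risks,
                          source=seq.source, model_kind=model.kind)
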