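"""Minimal numpy neural networks: an MLP and a single-layer LSTM.

Written for small tabular/sequence problems where full determinism matters
more than throughput: full-batch Adam, float64, a seeded initialiser and no
framework nondeterminism. Gradients are exact (verified against finite
differences in the test suite).
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy; returns (loss, dloss/dlogits)."""
    wsum = w.sum()
    # log(1 + exp(-|z|)) formulation is stable for large |z|
    loss = np.sum(w * (np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))
    p = _sigmoid(logits)
    return float(loss / wsum), w * (p - y) / wsum


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MLP:
    """Dense ReLU network with a single logit output."""

    def __init__(self, widths: tuple[int, ...], rng: np.random.Generator):
        self.widths = tuple(widths)
        self.params: dict[str, np.ndarray] = {}
        for i, (fan_in, fan_out) in enumerate(zip(widths[:-1], widths[1:])):
            scale = np.sqrt(2.0 / fan_in)
            self.params[f"W{i}"] = rng.normal(0.0, scale, size=(fan_in, fan_out))
            self.params[f"b{i}"] = np.zeros(fan_out)
        self.n_layers = len(widths) - 1

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        a = X
        cache = [a]
        for i in range(self.n_layers):
            z = a @ self.params[f"W{i}"] + self.params[f"b{i}"]
            a = np.maximum(z, 0.0) if i < self.n_layers - 1 else z
            cache.append(a)
        return a[:, 0], cache

    def predict(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(X)
        return _sigmoid(logits)

    def backward(self, cache: list, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        delta = dlogits[:, None]
        for i in range(self.n_layers - 1, -1, -1):
            a_prev = cache[i]
            grads[f"W{i}"] = a_prev.T @ delta
            grads[f"b{i}"] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.params[f"W{i}"].T) * (cache[i] > 0)
        return grads


class LSTMNet:
    """Per-fragment dense encoder -> single-layer LSTM -> per-step logit.

    Inputs are (B, T, F) with a boolean mask (B, T); the hidden state carries
    the accumulated history, so the step-t output depends only on fragments at
    times <= t (causality by construction).
    """

    def __init__(self, n_features: int, encoder_width: int, hidden_size: int,
                 rng: np.random.Generator):
        e, h = encoder_width, hidden_size
        self.e, self.h = e, h
        p: dict[str, np.ndarray] = {}
        p["We"] = rng.normal(0.0, np.sqrt(2.0 / n_features), size=(n_features, e))
        p["be"] = np.zeros(e)
        p["Wg"] = rng.normal(0.0, np.sqrt(1.0 / (e + h)), size=(e + h, 4 * h))
        bg = np.zeros(4 * h)
        bg[h:2 * h] = 1.0  # forget-gate bias init
        p["bg"] = bg
        p["Wy"] = rng.normal(0.0, np.sqrt(1.0 / h), size=(h, 1))
        p["by"] = np.zeros(1)
        self.params = p

    def forward(self, X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, dict]:
        B, T, _ = X.shape
        h, e = self.h, self.e
        p = self.params
        E = np.maximum(np.einsum("btf,fe->bte", X, p["We"]) + p["be"], 0.0)
        hs = np.zeros((B, T, h))
        cs = np.zeros((B, T, h))
        gates = np.zeros((B, T, 4 * h))
        h_t = np.zeros((B, h))
        c_t = np.zeros((B, h))
        for t in range(T):
            z = np.concatenate([E[:, t], h_t], axis=1) @ p["Wg"] + p["bg"]
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_t = f * c_t + i * g
            h_t = o * np.tanh(c_t)
            m = mask[:, t:t + 1]
            h_t = h_t * m
            c_t = c_t * m
            hs[:, t] = h_t
            cs[:, t] = c_t
            gates[:, t] = np.concatenate([i, f, g, o], axis=1)
        logits = (hs @ p["Wy"])[..., 0] + p["by"][0]
        cache = {"X": X, "E": E, "hs": hs, "cs": cs, "gates": gates, "mask": mask}
        return logits, cache

    def predict(self, X: np.ndarray, mask: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(X, mask)
        return _sigmoid(logits)

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        X, E, hs, cs, gates, mask = (cache[k] for k in ("X", "E", "hs", "cs", "gates", "mask"))
        B, T, h = hs.shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wy"] = np.einsum("bth,bt->h", hs, dlogits)[:, None]
        grads["by"] = np.array([dlogits.sum()])

        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        dE = np.zeros_like(E)
        for t in range(T - 1, -1, -1):
            m = mask[:, t:t + 1]
            dh = (dlogits[:, t:t + 1] * p["Wy"].T + dh_next) * m
            dc = dc_next * m
            i, f, g, o = (gates[:, t, k * h:(k + 1) * h] for k in range(4))
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, h))
            c_raw = f * c_prev + i * g  # pre-mask cell state
            tanh_c = np.tanh(c_raw)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g**2), do * o * (1 - o),
            ], axis=1)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, h))
            inp = np.concatenate([E[:, t], h_prev], axis=1)
            grads["Wg"] += inp.T @ dz
            grads["bg"] += dz.sum(axis=0)
            dinp = dz @ p["Wg"].T
            dE[:, t] = dinp[:, :self.e]
            dh_next = dinp[:, self.e:]
            dc_next = dc * f
        dZe = dE * (E > 0)
        grads["We"] = np.einsum("btf,bte->fe", X, dZe)
        grads["be"] = dZe.sum(axis=(0, 1))
        return grads
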