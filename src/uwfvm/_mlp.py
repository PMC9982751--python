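"""A compact feed-forward pixel classifier with explicit training control.

Deliberately small and self-contained: deterministic initialization from a
seed, epoch-level training via Adam on minibatches, and lossless
save/load, so the two-stage pretrain/fine-tune procedure can assert exact
properties (zero epochs leaves the weights untouched; identical seeds give
identical models).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TinyMLP:
    """Fully-connected net: input -> hidden(relu) -> 1 (sigmoid)."""

    n_features: int
    hidden: int = 16
    seed: int = 0
    learning_rate: float = 1e-3
    params: dict = field(default_factory=dict, repr=False)
    _adam: dict = field(default_factory=dict, repr=False)
    _step: int = 0

    def __post_init__(self) -> None:
        if not self.params:
            rng = np.random.default_rng(self.seed)
            scale1 = np.sqrt(2.0 / self.n_features)
            self.params = {
                "W1": rng.normal(0.0, scale1, (self.n_features, self.hidden)),
                "b1": np.zeros(self.hidden),
                "W2": rng.normal(0.0, np.sqrt(2.0 / self.hidden), (self.hidden, 1)),
                "b2": np.zeros(1),
            }
        if not self._adam:
            self._adam = {k: (np.zeros_like(v), np.zeros_like(v))
                          for k, v in self.params.items()}

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def _forward(self, X: np.ndarray):
        z1 = X @ self.params["W1"] + self.params["b1"]
        h = np.maximum(z1, 0.0)
        z2 = h @ self.params["W2"] + self.params["b2"]
        return z1, h, _sigmoid(z2[:, 0])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=np.float64))[2]

    def fit_epochs(self, X: np.ndarray, y: np.ndarray, epochs: int,
                   batch_size: int = 512, shuffle_seed: int = 0) -> "TinyMLP":
        """Adam/BCE training for a whole number of epochs (0 is a no-op)."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, d) with matching y")
        rng = np.random.default_rng(shuffle_seed)
        n = X.shape[0]
        for _ in range(int(epochs)):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start: start + batch_size]
                self._adam_step(X[idx], y[idx])
        return self

    def _adam_step(self, Xb: np.ndarray, yb: np.ndarray,
                   beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        m = Xb.shape[0]
        z1, h, p = self._forward(Xb)
        dz2 = (p - yb)[:, None] / m  # d BCE / d z2
        grads = {
            "W2": h.T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        dh = dz2 @ self.params["W2"].T
        dz1 = dh * (z1 > 0)
        grads["W1"] = Xb.T @ dz1
        grads["b1"] = dz1.sum(axis=0)

        self._step += 1
        t = self._step
        for k, g in grads.items():
            m1, m2 = self._adam[k]
            m1 = beta1 * m1 + (1 - beta1) * g
            m2 = beta2 * m2 + (1 - beta2) * g * g
            self._adam[k] = (m1, m2)
            mhat = m1 / (1 - beta1**t)
            vhat = m2 / (1 - beta2**t)
            self.params[k] = self.params[k] - self.learning_rate * mhat / (
                np.sqrt(vhat) + eps)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        meta = {"n_features": self.n_features, "hidden": self.hidden,
                "seed": self.seed, "learning_rate": self.learning_rate,
                "step": self._step}
        np.savez(path, meta=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "TinyMLP":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        model = cls(n_features=meta["n_features"], hidden=meta["hidden"],
                    seed=meta["seed"], learning_rate=meta["learning_rate"],
                    params={k: data[k] for k in ("W1", "b1", "W2", "b2")})
        model._step = meta["step"]
        return model
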