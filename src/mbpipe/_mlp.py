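"""A small deterministic feedforward binary classifier.

Architecture: input -> dense(100) -> ReLU -> dense(100) -> Sigmoid ->
dense(1) -> Sigmoid, trained with Adam (lr 0.005) on binary cross-entropy,
mini-batches of 16, for a fixed number of epochs (no early stopping, so
runs are deterministic and comparable across configurations).  All
randomness — weight initialization and batch shuffling — flows from the
constructor seed.
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


class FeedForwardNet:
    """Two-hidden-layer (100, 100) ReLU/Sigmoid net for binary targets."""

    def __init__(
        self,
        hidden: tuple[int, int] = (100, 100),
        learning_rate: float = 0.005,
        batch_size: int = 16,
        epochs: int = 100,
        seed: int = 0,
    ) -> None:
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FeedForwardNet":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).reshape(-1, 1)
        rng = np.random.default_rng(self.seed)
        sizes = [X.shape[1], *self.hidden, 1]
        # He-style init for the ReLU layer, Glorot for the sigmoid layers
        self.W_ = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(3)
        ]
        self.b_ = [np.zeros(sizes[i + 1]) for i in range(3)]

        m = [np.zeros_like(w) for w in self.W_] + [np.zeros_like(b) for b in self.b_]
        v = [np.zeros_like(w) for w in self.W_] + [np.zeros_like(b) for b in self.b_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                grads = self._backward(xb, yb)
                t += 1
                params = self.W_ + self.b_
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1**t)
                    vhat = v[i] / (1 - beta2**t)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
        return self

    def _forward(self, X: np.ndarray):
        z1 = X @ self.W_[0] + self.b_[0]
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.W_[1] + self.b_[1]
        a2 = _sigmoid(z2)
        z3 = a2 @ self.W_[2] + self.b_[2]
        p = _sigmoid(z3)
        return z1, a1, a2, p

    def _backward(self, X: np.ndarray, y: np.ndarray):
        z1, a1, a2, p = self._forward(X)
        nb = X.shape[0]
        # BCE + sigmoid output: delta simplifies to (p - y)
        d3 = (p - y) / nb
        gW3 = a2.T @ d3
        gb3 = d3.sum(axis=0)
        d2 = (d3 @ self.W_[2].T) * a2 * (1.0 - a2)
        gW2 = a1.T @ d2
        gb2 = d2.sum(axis=0)
        d1 = (d2 @ self.W_[1].T) * (z1 > 0)
        gW1 = X.T @ d1
        gb1 = d1.sum(axis=0)
        return [gW1, gW2, gW3, gb1, gb2, gb3]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        p = self._forward(X)[3].ravel()
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X)[:, 1]
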