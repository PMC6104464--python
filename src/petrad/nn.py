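"""A minimal fully-connected one-hidden-layer sigmoid network.

Written directly in numpy because the protocol needs per-case loss weights
(the positive class counts four-fold), deterministic seeded initialization,
an exact trainable-parameter count, and early stopping on a held-out
validation loss — all under tight control.  Training is full-batch Adam on
the weighted cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def n_parameters(n_inputs: int, n_hidden: int) -> int:
    """Trainable weights and biases: (n_inputs + 1) * h + (h + 1)."""
    return (n_inputs + 1) * n_hidden + (n_hidden + 1)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class TrainedNetwork:
    """Weights of one trained member, with its input normalization."""

    w1: np.ndarray  # (n_in, h)
    b1: np.ndarray  # (h,)
    w2: np.ndarray  # (h,)
    b2: float
    x_min: np.ndarray  # per-input train-set minima
    x_max: np.ndarray  # per-input train-set maxima
    seed: int = 0

    @property
    def n_parameters(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + 1

    def normalize(self, X: np.ndarray) -> np.ndarray:
        """Affine map taking the train-set min/max exactly to -1/+1."""
        return 2.0 * (X - self.x_min) / (self.x_max - self.x_min) - 1.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid outputs in (0, 1) for raw (unnormalized) inputs."""
        Z = self.normalize(np.atleast_2d(np.asarray(X, dtype=float)))
        h = _sigmoid(Z @ self.w1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)


def _weighted_bce(out: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    ll = y * np.log(out + eps) + (1 - y) * np.log(1 - out + eps)
    return float(-np.sum(w * ll) / np.sum(w))


def train_network_raw(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_hidden: int,
    positive_weight: float = 4.0,
    seed: int = 0,
    lr: float = 0.05,
    max_epochs: int = 500,
    patience: int = 25,
) -> TrainedNetwork:
    """Train one network; deterministic given ``seed``.

    Inputs are normalized to [-1, 1] from the training-set min/max (a
    constant training input is an error).  Early stopping restores the
    weights with the best validation loss (patience in epochs).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if not (set(np.unique(y_train)) == {0.0, 1.0}):
        raise ValueError("training set must contain both classes")

    x_min, x_max = X_train.min(axis=0), X_train.max(axis=0)
    degenerate = np.isclose(x_min, x_max)
    if degenerate.any():
        raise ValueError(f"constant training input at column(s) {np.where(degenerate)[0].tolist()}")

    rng = np.random.default_rng(seed)
    n_in = X_train.shape[1]
    w1 = rng.normal(0.0, 0.5, size=(n_in, n_hidden))
    b1 = rng.normal(0.0, 0.5, size=n_hidden)
    w2 = rng.normal(0.0, 0.5, size=n_hidden)
    b2 = float(rng.normal(0.0, 0.5))

    net = TrainedNetwork(w1, b1, w2, b2, x_min, x_max, seed)
    Zt = net.normalize(X_train)
    Zv = net.normalize(X_val)
    wt = np.where(y_train == 1, positive_weight, 1.0)
    wv = np.where(y_val == 1, positive_weight, 1.0)

    params = [w1, b1, w2, np.array([b2])]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    best = None
    best_loss = np.inf
    since_best = 0
    for t in range(1, max_epochs + 1):
        h = _sigmoid(Zt @ params[0] + params[1])
        out = _sigmoid(h @ params[2] + params[3][0])
        # gradient of the weighted cross-entropy wrt pre-activations
        delta_out = wt * (out - y_train) / wt.sum()
        g_w2 = h.T @ delta_out
        g_b2 = np.array([delta_out.sum()])
        delta_h = np.outer(delta_out, params[2]) * h * (1 - h)
        g_w1 = Zt.T @ delta_h
        g_b1 = delta_h.sum(axis=0)
        for p, g, mi, vi in zip(params, (g_w1, g_b1, g_w2, g_b2), m, v):
            mi *= beta1
            mi += (1 - beta1) * g
            vi *= beta2
            vi += (1 - beta2) * g**2
            p -= lr * (mi / (1 - beta1**t)) / (np.sqrt(vi / (1 - beta2**t)) + eps)

        hv = _sigmoid(Zv @ params[0] + params[1])
        val_loss = _weighted_bce(_sigmoid(hv @ params[2] + params[3][0]), y_val, wv)
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best = [p.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break

    if best is not None:
        params = best
    return TrainedNetwork(params[0], params[1], params[2], float(params[3][0]), x_min, x_max, seed)
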