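"""Compact fully-connected binary classifier in numpy.

ReLU hidden layers, single logistic output node, Glorot-uniform weight
initialization, RMSprop optimization of the binary cross entropy with
optional L1/L2 weight penalties and inverted dropout.  Everything is
seeded and deterministic; inputs are standardized internally using
training-set statistics so raw clinical feature scales do not matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLP", "TrainResult"]

_EPS = 1e-7


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float64)


@dataclass
class TrainResult:
    epochs_run: int
    best_epoch: int
    history: list[dict] = field(default_factory=list)


class MLP:
    """Feed-forward net with the given hidden-layer node counts."""

    def __init__(
        self,
        n_features: int,
        hidden: tuple[int, ...],
        seed: int = 0,
        l1: float = 0.0,
        l2: float = 0.0,
        dropout: float = 0.0,
    ):
        self.n_features = n_features
        self.hidden = tuple(int(h) for h in hidden)
        self.l1, self.l2, self.dropout = float(l1), float(l2), float(dropout)
        self.seed = seed
        rng = np.random.default_rng(seed)
        sizes = [n_features, *self.hidden, 1]
        self.W = [_glorot_uniform(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])]
        self.b = [np.zeros(b) for b in sizes[1:]]
        self._mu = np.zeros(n_features)
        self._sd = np.ones(n_features)
        self._rng = rng

    # -- forward ----------------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self._mu) / self._sd

    def _forward(self, Z: np.ndarray, train: bool = False):
        acts = [Z]
        h = Z
        masks = []
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            h = h @ W + b
            if i < len(self.W) - 1:
                np.maximum(h, 0.0, out=h)
                if train and self.dropout > 0:
                    m = (self._rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                    h = h * m
                    masks.append(m)
                else:
                    masks.append(None)
            acts.append(h)
        p = 1.0 / (1.0 + np.exp(-np.clip(acts[-1][:, 0], -30, 30)))
        return p, acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Raw scores in (0, 1); deterministic and row-wise."""
        X = np.asarray(X, dtype=np.float64)
        p, _, _ = self._forward(self._standardize(X), train=False)
        return np.clip(p, _EPS, 1 - _EPS)

    # -- training ---------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 30,
        minibatch_size: int = 10_000,
        learning_rate: float = 2e-4,
        rho: float = 0.9,
        callback=None,
        patience: int | None = None,
    ) -> TrainResult:
        """Minimize BCE with RMSprop on shuffled minibatches.

        ``callback(epoch, model) -> float`` is evaluated after each epoch;
        its value is maximized for checkpoint selection (weights of the
        best epoch are restored on return).  ``patience`` stops training
        after that many epochs without improvement.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        self._mu = X.mean(axis=0)
        self._sd = X.std(axis=0)
        self._sd[self._sd < 1e-8] = 1.0
        Z = self._standardize(X)

        cache_W = [np.zeros_like(w) for w in self.W]
        cache_b = [np.zeros_like(b) for b in self.b]
        n = len(y)
        mb = max(1, min(minibatch_size, n))
        best_val, best_epoch = -np.inf, -1
        best_weights = None
        result = TrainResult(epochs_run=0, best_epoch=-1)
        for epoch in range(epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, mb):
                idx = order[start:start + mb]
                zb, yb = Z[idx], y[idx]
                p, acts, masks = self._forward(zb, train=True)
                if not np.all(np.isfinite(p)):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                delta = ((p - yb) / len(yb))[:, None]  # dBCE/dlogit
                for i in range(len(self.W) - 1, -1, -1):
                    gW = acts[i].T @ delta
                    gb = delta.sum(axis=0)
                    if self.l2:
                        gW += self.l2 * self.W[i]
                    if self.l1:
                        gW += self.l1 * np.sign(self.W[i])
                    if i > 0:
                        delta = delta @ self.W[i].T
                        delta *= acts[i] > 0
                        if masks[i - 1] is not None:
                            delta *= masks[i - 1]
                    cache_W[i] = rho * cache_W[i] + (1 - rho) * gW * gW
                    cache_b[i] = rho * cache_b[i] + (1 - rho) * gb * gb
                    self.W[i] -= learning_rate * gW / (np.sqrt(cache_W[i]) + _EPS)
                    self.b[i] -= learning_rate * gb / (np.sqrt(cache_b[i]) + _EPS)
            result.epochs_run = epoch + 1
            if callback is not None:
                score = callback(epoch, self)
                if score > best_val:
                    best_val, best_epoch = score, epoch
                    best_weights = ([w.copy() for w in self.W],
                                    [b.copy() for b in self.b])
                elif patience is not None and epoch - best_epoch >= patience:
                    break
        if best_weights is not None:
            self.W, self.b = best_weights
            result.best_epoch = best_epoch
        return result

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "hidden": list(self.hidden),
            "l1": self.l1, "l2": self.l2, "dropout": self.dropout,
            "seed": self.seed,
            "mu": self._mu.tolist(), "sd": self._sd.tolist(),
            "W": [w.tolist() for w in self.W],
            "b": [b.tolist() for b in self.b],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLP":
        net = cls(d["n_features"], tuple(d["hidden"]), seed=d["seed"],
                  l1=d["l1"], l2=d["l2"], dropout=d["dropout"])
        net._mu = np.asarray(d["mu"], dtype=np.float64)
        net._sd = np.asarray(d["sd"], dtype=np.float64)
        net.W = [np.asarray(w, dtype=np.float64) for w in d["W"]]
        net.b = [np.asarray(b, dtype=np.float64) for b in d["b"]]
        return net
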