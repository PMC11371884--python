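"""Feed-forward binary classifier on ray-feature vectors.

The network maps the N joint-gap distances (mm) of one temporomandibular
joint to a confidence in (0, 1) that the condyle is incorrectly seated.
Architecture: dense hidden layers of 192, 128, 64 and 32 units, ReLU
activations, each followed by batch normalization (momentum 0.8) and
dropout (rate 0.25); a single sigmoid output unit.

Training uses Adam with a decaying triangular ("triangular2") cyclic
learning rate oscillating between 5e-5 and 5e-4 with a half-period of
2,000 optimizer iterations, weighted binary cross-entropy (class balancing
w_c = n_total / (2 n_c)), batch size 32.  A fixed confidence cutoff
(default 0.2) converts the output to a label: incorrect iff
confidence >= cutoff.  The low cutoff trades precision for sensitivity —
the tool is meant to alert the surgeon to possible seating problems.

The implementation is plain numpy (forward, backprop and the optimizer are
written out explicitly) and fully reproducible from a single seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

_BN_EPS = 1e-5


@dataclass(frozen=True)
class NetworkSpec:
    input_dim: int = 198
    hidden_sizes: tuple = (192, 128, 64, 32)
    dropout_rate: float = 0.25
    bn_momentum: float = 0.8

    def __post_init__(self) -> None:
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be nonempty")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 0 < self.bn_momentum < 1:
            raise ValueError("bn_momentum must lie in (0, 1)")

    def n_dense_parameters(self) -> int:
        """Trainable dense weights + biases, excluding batch-norm affines."""
        sizes = (self.input_dim, *self.hidden_sizes, 1)
        return sum(a * b + b for a, b in zip(sizes[:-1], sizes[1:]))


@dataclass(frozen=True)
class TrainingConfig:
    base_lr: float = 5e-5
    max_lr: float = 5e-4
    step_size: int = 2000  # optimizer iterations per half-cycle
    lr_policy: str = "triangular2"
    batch_size: int = 32
    epochs: int = 1000
    class_balancing: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.base_lr < self.max_lr:
            raise ValueError("base_lr must be < max_lr")
        if self.step_size < 1 or self.batch_size < 1:
            raise ValueError("step_size and batch_size must be >= 1")
        if self.lr_policy not in ("triangular", "triangular2"):
            raise ValueError(f"unknown lr_policy {self.lr_policy!r}")


@dataclass(frozen=True)
class PredictionConfig:
    cutoff: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")


def cyclic_lr(iteration: int, cfg: TrainingConfig) -> float:
    """Triangular cyclic learning rate at a given optimizer iteration.

    The rate ramps linearly from base_lr to max_lr over ``step_size``
    iterations and back; under ``triangular2`` the amplitude halves after
    each full cycle.  lr(0) = base_lr.
    """
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    cycle = int(np.floor(1 + iteration / (2 * cfg.step_size)))
    x = abs(iteration / cfg.step_size - 2 * cycle + 1)
    scale = 1.0 if cfg.lr_policy == "triangular" else 1.0 / (2 ** (cycle - 1))
    return cfg.base_lr + (cfg.max_lr - cfg.base_lr) * max(0.0, 1.0 - x) * scale


def class_weights(labels: Sequence[int]) -> tuple[float, float]:
    """Balancing weights (w_negative, w_positive): w_c = n_total / (2 n_c)."""
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to balance them")
    n = y.size
    return n / (2.0 * n_neg), n / (2.0 * n_pos)


class FeedForwardClassifier:
    """Dense ReLU network with per-layer batch norm and dropout (numpy)."""

    def __init__(self, net: NetworkSpec, cfg: Optional[TrainingConfig] = None):
        self.net = net
        self.cfg = cfg or TrainingConfig()
        self._rng = np.random.default_rng(self.cfg.rng_seed)
        self._init_params()
        self.loss_trace: list = []
        self._iteration = 0
        self.fitted = False

    # -- parameters --------------------------------------------------------

    def _init_params(self) -> None:
        sizes = (self.net.input_dim, *self.net.hidden_sizes, 1)
        self.W, self.b = [], []
        for a, c in zip(sizes[:-1], sizes[1:]):
            # He initialisation for the ReLU layers
            self.W.append(self._rng.normal(0.0, np.sqrt(2.0 / a), size=(a, c)))
            self.b.append(np.zeros(c))
        h = self.net.hidden_sizes
        self.gamma = [np.ones(s) for s in h]
        self.beta = [np.zeros(s) for s in h]
        self.running_mean = [np.zeros(s) for s in h]
        self.running_var = [np.ones(s) for s in h]
        params = self.W + self.b + self.gamma + self.beta
        self._adam_m = [np.zeros_like(p) for p in params]
        self._adam_v = [np.zeros_like(p) for p in params]

    def _params(self) -> list:
        return self.W + self.b + self.gamma + self.beta

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, training: bool):
        cache = {"h": [X], "z": [], "a": [], "xhat": [], "std": [], "mu": [],
                 "drop": []}
        h = X
        mom = self.net.bn_momentum
        for li, _ in enumerate(self.net.hidden_sizes):
            z = h @ self.W[li] + self.b[li]
            a = np.maximum(z, 0.0)
            if training:
                mu = a.mean(axis=0)
                var = a.var(axis=0)
                # running_stat <- momentum*running_stat + (1-momentum)*batch_stat
                self.running_mean[li] = mom * self.running_mean[li] + (1 - mom) * mu
                self.running_var[li] = mom * self.running_var[li] + (1 - mom) * var
            else:
                mu = self.running_mean[li]
                var = self.running_var[li]
            std = np.sqrt(var + _BN_EPS)
            xhat = (a - mu) / std
            y = self.gamma[li] * xhat + self.beta[li]
            if training and self.net.dropout_rate > 0:
                keep = 1.0 - self.net.dropout_rate
                mask = (self._rng.random(y.shape) < keep) / keep
                y = y * mask
            else:
                mask = None
            cache["z"].append(z)
            cache["a"].append(a)
            cache["xhat"].append(xhat)
            cache["std"].append(std)
            cache["mu"].append(mu)
            cache["drop"].append(mask)
            cache["h"].append(y)
            h = y
        logits = h @ self.W[-1] + self.b[-1]
        p = 1.0 / (1.0 + np.exp(-logits))
        return p.ravel(), cache

    def _backward(self, p, y, w, cache):
        nL = len(self.net.hidden_sizes)
        m = y.size
        dW = [None] * len(self.W)
        db = [None] * len(self.b)
        dgamma = [None] * nL
        dbeta = [None] * nL
        # weighted BCE, mean over batch: dL/dlogit = w*(p - y)/m
        dlogit = (w * (p - y) / m)[:, None]
        h_last = cache["h"][-1]
        dW[-1] = h_last.T @ dlogit
        db[-1] = dlogit.sum(axis=0)
        dh = dlogit @ self.W[-1].T
        for li in range(nL - 1, -1, -1):
            if cache["drop"][li] is not None:
                dh = dh * cache["drop"][li]
            xhat = cache["xhat"][li]
            std = cache["std"][li]
            dgamma[li] = (dh * xhat).sum(axis=0)
            dbeta[li] = dh.sum(axis=0)
            dxhat = dh * self.gamma[li]
            mb = xhat.shape[0]
            da = (dxhat - dxhat.mean(axis=0) - xhat * (dxhat * xhat).mean(axis=0)) / std
            dz = da * (cache["z"][li] > 0)
            dW[li] = cache["h"][li].T @ dz
            db[li] = dz.sum(axis=0)
            dh = dz @ self.W[li].T
        return dW + db + dgamma + dbeta

    def _adam_step(self, grads: list, lr: float) -> None:
        params = self._params()
        t = self._iteration + 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * g
            self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * g * g
            mhat = self._adam_m[i] / (1 - b1**t)
            vhat = self._adam_v[i] / (1 - b2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- training -----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: Sequence[int],
        epochs: Optional[int] = None,
    ) -> "FeedForwardClassifier":
        """Train on a fixed feature matrix (no per-epoch re-extraction)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(float).ravel()
        return self.fit_stream(lambda epoch: (X, y), y, epochs=epochs)

    def fit_stream(
        self,
        provider: Callable[[int], tuple],
        all_labels: Sequence[int],
        epochs: Optional[int] = None,
    ) -> "FeedForwardClassifier":
        """Train with per-epoch feature re-extraction.

        ``provider(epoch)`` returns the (X, y) used for that epoch (the
        augmentation hook: features re-cast under a freshly sampled rigid
        perturbation).  Class-balancing weights are computed once from
        ``all_labels``.
        """
        epochs = self.cfg.epochs if epochs is None else epochs
        y_all = np.asarray(all_labels).astype(float).ravel()
        if self.cfg.class_balancing:
            w_neg, w_pos = class_weights(y_all)
        else:
            if y_all.min() == y_all.max():
                raise ValueError("both classes must be present for training")
            w_neg = w_pos = 1.0
        for epoch in range(epochs):
            X, y = provider(epoch)
            X = np.asarray(X, dtype=float)
            y = np.asarray(y).astype(float).ravel()
            if X.shape[1] != self.net.input_dim:
                raise ValueError(
                    f"feature width {X.shape[1]} != input_dim {self.net.input_dim}"
                )
            order = self._rng.permutation(y.size)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, y.size, self.cfg.batch_size):
                sel = order[start : start + self.cfg.batch_size]
                Xb, yb = X[sel], y[sel]
                wb = np.where(yb > 0.5, w_pos, w_neg)
                p, cache = self._forward(Xb, training=True)
                p_c = np.clip(p, 1e-12, 1 - 1e-12)
                loss = float(
                    np.mean(wb * -(yb * np.log(p_c) + (1 - yb) * np.log(1 - p_c)))
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, iteration "
                        f"{self._iteration}: {loss}"
                    )
                grads = self._backward(p, yb, wb, cache)
                lr = cyclic_lr(self._iteration, self.cfg)
                self._adam_step(grads, lr)
                self._iteration += 1
                epoch_loss += loss
                n_batches += 1
            self.loss_trace.append(epoch_loss / max(n_batches, 1))
        self.fitted = True
        return self

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Confidence in (0, 1) per joint; inference mode (running BN stats)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.net.input_dim:
            raise ValueError(
                f"feature width {X.shape[1]} != input_dim {self.net.input_dim}"
            )
        p, _ = self._forward(X, training=False)
        return p

    def predict(
        self, X: np.ndarray, pcfg: Optional[PredictionConfig] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (confidences, labels); label = incorrect iff conf >= cutoff."""
        pcfg = pcfg or PredictionConfig()
        p = self.predict_proba(X)
        return p, p >= pcfg.cutoff

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Serialise weights + specs to a single .npz checkpoint."""
        arrays = {}
        for name, group in (
            ("W", self.W), ("b", self.b), ("gamma", self.gamma),
            ("beta", self.beta), ("rmean", self.running_mean),
            ("rvar", self.running_var),
        ):
            for i, arr in enumerate(group):
                arrays[f"{name}_{i}"] = arr
        arrays["meta"] = np.frombuffer(
            json.dumps(
                {"net": asdict(self.net), "cfg": asdict(self.cfg)}
            ).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "FeedForwardClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["meta"]).decode())
        meta["net"]["hidden_sizes"] = tuple(meta["net"]["hidden_sizes"])
        model = cls(NetworkSpec(**meta["net"]), TrainingConfig(**meta["cfg"]))
        nL = len(model.net.hidden_sizes)
        model.W = [data[f"W_{i}"] for i in range(nL + 1)]
        model.b = [data[f"b_{i}"] for i in range(nL + 1)]
        model.gamma = [data[f"gamma_{i}"] for i in range(nL)]
        model.beta = [data[f"beta_{i}"] for i in range(nL)]
        model.running_mean = [data[f"rmean_{i}"] for i in range(nL)]
        model.running_var = [data[f"rvar_{i}"] for i in range(nL)]
        model.fitted = True
        return model
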