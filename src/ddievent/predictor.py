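"""Stage 2: ensemble of fully connected sub-networks, one per source.

Each sub-network is a bottleneck-style stack
input -> hidden_1 -> ... -> hidden_k -> R with batch normalization,
ReLU and dropout after every hidden layer and a softmax output over the
R event classes.  Sub-networks are trained independently on their
source's pair-feature matrix against the shared labels with
cross-entropy and Adam; early stopping watches validation loss on a
stratified split of the training rows (patience 10 by default) and
restores the best-epoch weights.  The ensemble prediction is the
arithmetic mean of the per-sub-network softmax outputs.

Implemented directly in NumPy: the networks are small (two hidden
layers on a few-thousand-row input) and a self-contained trainer keeps
runs bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .aggregate import PairFeatureSet
from .io_model import ValidationError


@dataclass(frozen=True)
class PredictorConfig:
    hidden_sizes: tuple[int, ...] = (512, 256)
    dropout_rate: float = 0.3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    learning_rate: float = 1e-3
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if not 0 < self.validation_fraction <= 0.5:
            raise ValidationError("validation_fraction must be in (0, 0.5]")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _AdamState:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / (1 - b1**self.t)) / (
                np.sqrt(v / (1 - b2**self.t)) + eps
            )


class SubNetwork:
    """One fully connected classifier head for a single feature source."""

    def __init__(self, input_dim: int, n_classes: int, cfg: PredictorConfig,
                 rng: np.random.Generator):
        if input_dim < 1:
            raise ValidationError("input_dim must be >= 1")
        self.cfg = cfg
        self.n_classes = n_classes
        dims = [input_dim, *cfg.hidden_sizes, n_classes]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / dims[k]), size=(dims[k], dims[k + 1]))
            for k in range(len(dims) - 1)
        ]
        self.biases = [np.zeros(dims[k + 1]) for k in range(len(dims) - 1)]
        n_hidden = len(cfg.hidden_sizes)
        self.bn_gamma = [np.ones(h) for h in cfg.hidden_sizes]
        self.bn_beta = [np.zeros(h) for h in cfg.hidden_sizes]
        self.bn_mean = [np.zeros(h) for h in cfg.hidden_sizes]
        self.bn_var = [np.ones(h) for h in cfg.hidden_sizes]
        self._n_hidden = n_hidden

    def parameter_count(self) -> int:
        n = sum(w.size for w in self.weights) + sum(b.size for b in self.biases)
        n += sum(g.size for g in self.bn_gamma) + sum(b.size for b in self.bn_beta)
        return n

    def _parameters(self) -> list[np.ndarray]:
        return [*self.weights, *self.biases, *self.bn_gamma, *self.bn_beta]

    def snapshot(self) -> list[np.ndarray]:
        return [p.copy() for p in self._parameters()] + [
            m.copy() for m in self.bn_mean
        ] + [v.copy() for v in self.bn_var]

    def restore(self, snap: list[np.ndarray]) -> None:
        params = self._parameters()
        for p, s in zip(params, snap[: len(params)]):
            p[...] = s
        rest = snap[len(params):]
        for k in range(self._n_hidden):
            self.bn_mean[k][...] = rest[k]
            self.bn_var[k][...] = rest[self._n_hidden + k]

    def forward(
        self, x: np.ndarray, training: bool, rng: np.random.Generator | None = None
    ):
        """Returns (probs, cache); cache is needed only for backward."""
        eps = 1e-5
        cache = {"x": x, "h": [], "bn": [], "relu": [], "drop": []}
        h = x
        for k in range(self._n_hidden):
            z = h @ self.weights[k] + self.biases[k]
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                # running stats for inference, momentum 0.9
                self.bn_mean[k] = 0.9 * self.bn_mean[k] + 0.1 * mu
                self.bn_var[k] = 0.9 * self.bn_var[k] + 0.1 * var
            else:
                mu, var = self.bn_mean[k], self.bn_var[k]
            zhat = (z - mu) / np.sqrt(var + eps)
            a = self.bn_gamma[k] * zhat + self.bn_beta[k]
            relu_mask = a > 0
            a = a * relu_mask
            if training and self.cfg.dropout_rate > 0:
                keep = 1.0 - self.cfg.dropout_rate
                drop_mask = (rng.random(a.shape) < keep) / keep
                a = a * drop_mask
            else:
                drop_mask = None
            cache["h"].append(h)
            cache["bn"].append((z, zhat, mu, var))
            cache["relu"].append(relu_mask)
            cache["drop"].append(drop_mask)
            h = a
        logits = h @ self.weights[-1] + self.biases[-1]
        cache["last_in"] = h
        return _softmax(logits), cache

    def backward(self, probs: np.ndarray, y: np.ndarray, cache: dict):
        """Cross-entropy gradients for all trainable parameters."""
        eps = 1e-5
        b = probs.shape[0]
        delta = probs.copy()
        delta[np.arange(b), y] -= 1.0
        delta /= b
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        grads_g = [None] * self._n_hidden
        grads_be = [None] * self._n_hidden
        grads_w[-1] = cache["last_in"].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        da = delta @ self.weights[-1].T
        for k in range(self._n_hidden - 1, -1, -1):
            if cache["drop"][k] is not None:
                da = da * cache["drop"][k]
            da = da * cache["relu"][k]
            z, zhat, mu, var = cache["bn"][k]
            grads_g[k] = (da * zhat).sum(axis=0)
            grads_be[k] = da.sum(axis=0)
            dzhat = da * self.bn_gamma[k]
            inv_std = 1.0 / np.sqrt(var + eps)
            dz = (
                dzhat
                - dzhat.mean(axis=0)
                - zhat * (dzhat * zhat).mean(axis=0)
            ) * inv_std
            grads_w[k] = cache["h"][k].T @ dz
            grads_b[k] = dz.sum(axis=0)
            da = dz @ self.weights[k].T
        return [*grads_w, *grads_b, *grads_g, *grads_be]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(x, training=False)
        return probs


def build_subnetwork(
    input_dim: int, n_classes: int, cfg: PredictorConfig
) -> SubNetwork:
    return SubNetwork(input_dim, n_classes, cfg, np.random.default_rng(cfg.seed))


def _stratified_val_split(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (train, val); at least one val row per class with >= 2 rows."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = int(round(len(idx) * fraction))
        if len(idx) >= 2:
            n_val = max(n_val, 1)
        n_val = min(n_val, len(idx) - 1)
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


class EnsemblePredictor:
    """Trained sub-networks plus bookkeeping for prediction."""

    def __init__(self, subnetworks: list[SubNetwork], sources: tuple[str, ...],
                 n_classes: int):
        self.subnetworks = subnetworks
        self.sources = sources
        self.n_classes = n_classes

    def predict_proba(self, features: PairFeatureSet) -> np.ndarray:
        if features.sources != self.sources:
            raise ValidationError(
                f"feature sources {features.sources} do not match "
                f"training sources {self.sources}"
            )
        probs = [
            net.predict_proba(m) for net, m in zip(self.subnetworks, features.matrices)
        ]
        return np.mean(probs, axis=0)

    def predict(self, features: PairFeatureSet) -> np.ndarray:
        return self.predict_proba(features).argmax(axis=1)


def train_predictor(
    features: PairFeatureSet,
    labels: np.ndarray | None = None,
    cfg: PredictorConfig = PredictorConfig(),
    n_classes: int | None = None,
) -> EnsemblePredictor:
    """Train one sub-network per source with early stopping.

    ``labels`` defaults to the edge-list labels carried by the feature
    set.  Classes absent from the training labels stay in the output
    space (a warning is issued) so folds with missing rare events keep a
    consistent probability layout.
    """
    y = features.labels if labels is None else np.asarray(labels)
    if y.shape[0] != features.n_pairs:
        raise ValidationError("labels not aligned with pair features")
    if n_classes is None:
        n_classes = int(y.max()) + 1
    missing = sorted(set(range(n_classes)) - set(np.unique(y).tolist()))
    if missing:
        warnings.warn(
            f"{len(missing)} event class(es) absent from training labels "
            f"(kept in output space): {missing[:8]}",
            stacklevel=2,
        )

    master = np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 104729])
    seeds = master.spawn(len(features.matrices) + 1)
    split_rng = np.random.default_rng(seeds[-1])
    tr_idx, va_idx = _stratified_val_split(y, cfg.validation_fraction, split_rng)

    nets = []
    for src_k, x in enumerate(features.matrices):
        rng = np.random.default_rng(seeds[src_k])
        net = SubNetwork(x.shape[1], n_classes, cfg, rng)
        xtr, ytr = x[tr_idx], y[tr_idx]
        xva, yva = x[va_idx], y[va_idx]
        best_loss, best_snap, stale = np.inf, None, 0
        epochs_run = 0
        for _epoch in range(cfg.max_epochs):
            epochs_run += 1
            order = rng.permutation(len(xtr))
            for lo in range(0, len(order), cfg.batch_size):
                sel = order[lo: lo + cfg.batch_size]
                if sel.size < 2:
                    continue  # batch norm needs >= 2 rows
                probs, cache = net.forward(xtr[sel], training=True, rng=rng)
                grads = net.backward(probs, ytr[sel], cache)
                if not hasattr(net, "_opt"):
                    net._opt = _AdamState(net._parameters(), cfg.learning_rate)
                net._opt.step(net._parameters(), grads)
            val_probs = net.predict_proba(xva)
            val_loss = -np.mean(
                np.log(np.maximum(val_probs[np.arange(len(yva)), yva], 1e-12))
            )
            if val_loss < best_loss - 1e-6:
                best_loss, best_snap, stale = val_loss, net.snapshot(), 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        if best_snap is not None:
            net.restore(best_snap)
        net.epochs_run_ = epochs_run
        nets.append(net)
    return EnsemblePredictor(nets, features.sources, n_classes)


def predict(model: EnsemblePredictor, features: PairFeatureSet) -> np.ndarray:
    """Final event probabilities: mean of the per-sub-network softmaxes."""
    return model.predict_proba(features)
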