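"""The two-class classifier head and its training protocol.

Architecture: batch normalization -> 256-unit dense (ReLU, L2 kernel
regularizer 0.016, L1 activity and bias regularizers 0.006) -> dropout
0.45 -> 2-unit softmax.  Trained with Adamax on sparse categorical
cross-entropy, early stopping on validation loss (patience 5, best
weights restored) and learning-rate reduction on plateau (factor 0.2,
patience 4).  Implemented directly in numpy: forward, backward and the
optimizer are a few dense matrix expressions, which keeps the head fully
deterministic under its seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .data import FeatureTable

__all__ = ["HeadConfig", "TrainedHead", "train_head", "predict", "predict_proba"]


@dataclass(frozen=True)
class HeadConfig:
    """Hyperparameters of the classification layers and their training."""

    bn_momentum: float = 0.99
    bn_epsilon: float = 0.001
    dense_units: int = 256
    kernel_l2: float = 0.016
    activity_l1: float = 0.006
    bias_l1: float = 0.006
    dropout_rate: float = 0.45
    epochs: int = 100
    batch_size: int = 128
    learning_rate: float = 0.001
    early_stop_patience: int = 5
    early_stop_min_delta: float = 0.0
    lr_reduce_factor: float = 0.2
    lr_reduce_patience: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in (0, 1)")
        if self.early_stop_patience < 1 or self.lr_reduce_patience < 1:
            raise ValueError("patience values must be at least 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class TrainedHead:
    """Learned weights, the config that produced them and the epoch log."""

    weights: Dict[str, np.ndarray]
    config: HeadConfig
    training_log: List[dict] = field(default_factory=list)
    n_features: int = 0


def _init_weights(d: int, units: int, rng: np.random.Generator) -> Dict[str, np.ndarray]:
    lim1 = np.sqrt(6.0 / (d + units))
    lim2 = np.sqrt(6.0 / (units + 2))
    return {
        "gamma": np.ones(d),
        "beta": np.zeros(d),
        "run_mean": np.zeros(d),
        "run_var": np.ones(d),
        "W1": rng.uniform(-lim1, lim1, size=(d, units)),
        "b1": np.zeros(units),
        "W2": rng.uniform(-lim2, lim2, size=(units, 2)),
        "b2": np.zeros(2),
    }


_TRAINABLE = ("gamma", "beta", "W1", "b1", "W2", "b2")


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_inference(w: Dict[str, np.ndarray], x: np.ndarray,
                       cfg: HeadConfig) -> np.ndarray:
    xhat = (x - w["run_mean"]) / np.sqrt(w["run_var"] + cfg.bn_epsilon)
    z = w["gamma"] * xhat + w["beta"]
    a = np.maximum(z @ w["W1"] + w["b1"], 0.0)
    return _softmax(a @ w["W2"] + w["b2"])


def _penalties(w: Dict[str, np.ndarray], a: np.ndarray, cfg: HeadConfig) -> float:
    act = cfg.activity_l1 * float(np.abs(a).sum(axis=1).mean()) if len(a) else 0.0
    return (
        cfg.kernel_l2 * float(np.sum(w["W1"] ** 2))
        + cfg.bias_l1 * float(np.sum(np.abs(w["b1"])))
        + act
    )


def _eval_loss_acc(w: Dict[str, np.ndarray], x: np.ndarray, y: np.ndarray,
                   cfg: HeadConfig) -> Tuple[float, float]:
    xhat = (x - w["run_mean"]) / np.sqrt(w["run_var"] + cfg.bn_epsilon)
    z = w["gamma"] * xhat + w["beta"]
    a = np.maximum(z @ w["W1"] + w["b1"], 0.0)
    probs = _softmax(a @ w["W2"] + w["b2"])
    ce = float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())
    acc = float((probs.argmax(axis=1) == y).mean())
    return ce + _penalties(w, a, cfg), acc


def train_head(train: FeatureTable, val: FeatureTable, config: HeadConfig) -> TrainedHead:
    """Train the head on ``train``, monitoring ``val`` for early stopping.

    Deterministic under ``config.seed`` (weight init, batch shuffling and
    dropout masks all come from one generator).
    """
    if train.n_samples == 0 or val.n_samples == 0:
        raise ValueError("train and validation tables must be non-empty")
    if train.n_features != val.n_features:
        raise ValueError(
            f"dimension mismatch: train has {train.n_features} features, "
            f"val has {val.n_features}"
        )
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training set contains a single class")

    cfg = config
    rng = np.random.default_rng(cfg.seed)
    d = train.n_features
    w = _init_weights(d, cfg.dense_units, rng)
    m = {k: np.zeros_like(w[k]) for k in _TRAINABLE}
    u = {k: np.zeros_like(w[k]) for k in _TRAINABLE}
    step = 0
    lr = cfg.learning_rate
    beta1, beta2, opt_eps = 0.9, 0.999, 1e-7

    x_train, y_train = train.features, train.labels
    x_val, y_val = val.features, val.labels
    keep = 1.0 - cfg.dropout_rate

    best_loss = np.inf
    best_weights = None
    es_wait = 0
    lr_wait = 0
    log: List[dict] = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(x_train))
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x, y = x_train[idx], y_train[idx]
            B = len(x)

            # forward (training mode: batch statistics, dropout on)
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            inv_std = 1.0 / np.sqrt(var + cfg.bn_epsilon)
            xhat = (x - mu) * inv_std
            z = w["gamma"] * xhat + w["beta"]
            h = z @ w["W1"] + w["b1"]
            a = np.maximum(h, 0.0)
            mask = (rng.random(a.shape) >= cfg.dropout_rate) / keep
            a_drop = a * mask
            logits = a_drop @ w["W2"] + w["b2"]
            probs = _softmax(logits)

            ce = float(-np.log(np.clip(probs[np.arange(B), y], 1e-12, None)).mean())
            epoch_loss += (ce + _penalties(w, a, cfg)) * B
            epoch_correct += int((probs.argmax(axis=1) == y).sum())

            # running stats start at the first batch's statistics, which
            # avoids a cold-start train/inference mismatch under the slow
            # 0.99 momentum
            if step == 0:
                w["run_mean"], w["run_var"] = mu.copy(), var.copy()
            else:
                w["run_mean"] = cfg.bn_momentum * w["run_mean"] + (1 - cfg.bn_momentum) * mu
                w["run_var"] = cfg.bn_momentum * w["run_var"] + (1 - cfg.bn_momentum) * var

            # backward
            dlogits = probs.copy()
            dlogits[np.arange(B), y] -= 1.0
            dlogits /= B
            grads = {
                "W2": a_drop.T @ dlogits,
                "b2": dlogits.sum(axis=0),
            }
            da = dlogits @ w["W2"].T * mask
            da += cfg.activity_l1 * np.sign(a) / B  # activity regularizer
            dh = da * (h > 0.0)
            grads["W1"] = z.T @ dh + 2.0 * cfg.kernel_l2 * w["W1"]
            grads["b1"] = dh.sum(axis=0) + cfg.bias_l1 * np.sign(w["b1"])
            dz = dh @ w["W1"].T
            grads["gamma"] = (dz * xhat).sum(axis=0)
            grads["beta"] = dz.sum(axis=0)

            # Adamax update
            step += 1
            for k in _TRAINABLE:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                u[k] = np.maximum(beta2 * u[k], np.abs(grads[k]))
                w[k] = w[k] - (lr / (1 - beta1**step)) * m[k] / (u[k] + opt_eps)

        val_loss, val_acc = _eval_loss_acc(w, x_val, y_val, cfg)
        log.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / len(x_train),
                "train_accuracy": epoch_correct / len(x_train),
                "val_loss": val_loss,
                "val_accuracy": val_acc,
                "lr": lr,
            }
        )

        if val_loss < best_loss - cfg.early_stop_min_delta:
            best_loss = val_loss
            best_weights = copy.deepcopy(w)
            es_wait = 0
            lr_wait = 0
        else:
            es_wait += 1
            lr_wait += 1
            if lr_wait >= cfg.lr_reduce_patience:
                lr *= cfg.lr_reduce_factor
                lr_wait = 0
            if es_wait >= cfg.early_stop_patience:
                break

    final = best_weights if best_weights is not None else w
    return TrainedHead(weights=final, config=cfg, training_log=log, n_features=d)


def predict_proba(head: TrainedHead, table: FeatureTable) -> np.ndarray:
    """Two-class probabilities, one row per sample (rows sum to 1)."""
    if table.n_samples == 0:
        return np.zeros((0, 2))
    if table.n_features != head.n_features:
        raise ValueError(
            f"dimension mismatch: head trained on {head.n_features} features, "
            f"table has {table.n_features}"
        )
    return _forward_inference(head.weights, table.features, head.config)


def predict(head: TrainedHead, table: FeatureTable) -> Tuple[np.ndarray, np.ndarray]:
    """Predicted labels and class-1 probabilities."""
    probs = predict_proba(head, table)
    labels = probs.argmax(axis=1).astype(int) if len(probs) else np.zeros(0, dtype=int)
    return labels, probs[:, 1]
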