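"""Feed-forward neural-network comparator for the preprocessed spectra.

A compact fully-connected network — Dense(128, ReLU), Dense(64, ReLU),
linear 2-node output with softmax folded into a categorical cross-entropy
loss — trained with Adam (lr 0.001) in minibatches of 4.  The network
consumes the preprocessed (trimmed, smoothed, pin-normalized) spectra
directly: no PCA, the hidden layers do their own feature extraction.

Training is repeated five times from independent initializations (distinct
seeds derived from one master seed) and curves/metrics are averaged across
repeats, so a single lucky initialization cannot flatter the comparison.
The optimal epoch is read off the averaged validation-loss curve after the
fact rather than via early stopping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .bench import MetricsReport, evaluate_classifier

POSITIVE = "sarcoma"
NEGATIVE = "healthy"
CLASS_ORDER = (NEGATIVE, POSITIVE)  # column order of the 2-node output


@dataclass(frozen=True)
class ANNConfig:
    hidden_sizes: Tuple[int, int] = (128, 64)
    n_classes: int = 2
    learning_rate: float = 0.001
    batch_size: int = 4
    epochs: int = 100
    repeats: int = 5
    seed: int = 20241009

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.repeats < 1:
            raise ValueError("epochs, batch_size and repeats must be >= 1")


def parameter_count(n_features: int, config: ANNConfig = ANNConfig()) -> int:
    """Weights + biases: (F*128 + 128) + (128*64 + 64) + (64*2 + 2)."""
    h1, h2 = config.hidden_sizes
    return (n_features * h1 + h1) + (h1 * h2 + h2) + (h2 * config.n_classes + config.n_classes)


def _one_hot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((y.size, len(CLASS_ORDER)))
    for j, cls in enumerate(CLASS_ORDER):
        out[y == cls, j] = 1.0
    if not np.all(out.sum(axis=1) == 1.0):
        raise ValueError(f"labels must be among {CLASS_ORDER}")
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MLP:
    """Two-hidden-layer ReLU network with Adam and softmax cross-entropy."""

    def __init__(self, n_features: int, config: ANNConfig, seed: int) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        sizes = (n_features, *config.hidden_sizes, config.n_classes)
        self.weights: List[np.ndarray] = []
        self.biases: List[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self._adam_m = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_v = [np.zeros_like(w) for w in self.weights + self.biases]
        self._adam_t = 0
        self._rng = rng
        self.classes_ = np.array(CLASS_ORDER)

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights) + sum(b.size for b in self.biases))

    def _forward(self, X: np.ndarray) -> Tuple[np.ndarray, List[np.ndarray]]:
        activations = [X]
        a = X
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ w + b, 0.0)
            activations.append(a)
        logits = a @ self.weights[-1] + self.biases[-1]
        return logits, activations

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(np.asarray(X, dtype=float))
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def loss_accuracy(self, X: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
        """Mean categorical cross-entropy and accuracy on (X, y)."""
        targets = _one_hot(np.asarray(y))
        proba = self.predict_proba(X)
        eps = 1e-12
        loss = float(-np.mean(np.sum(targets * np.log(proba + eps), axis=1)))
        acc = float(np.mean(self.predict(X) == np.asarray(y)))
        return loss, acc

    def _adam_step(self, grads: List[np.ndarray]) -> None:
        cfg = self.config
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        params = self.weights + self.biases
        for i, (p, g) in enumerate(zip(params, grads)):
            self._adam_m[i] = beta1 * self._adam_m[i] + (1 - beta1) * g
            self._adam_v[i] = beta2 * self._adam_v[i] + (1 - beta2) * g * g
            m_hat = self._adam_m[i] / (1 - beta1**self._adam_t)
            v_hat = self._adam_v[i] / (1 - beta2**self._adam_t)
            p -= cfg.learning_rate * m_hat / (np.sqrt(v_hat) + eps)

    def train_epoch(self, X: np.ndarray, targets: np.ndarray) -> None:
        """One shuffled pass of minibatch Adam updates."""
        n = X.shape[0]
        order = self._rng.permutation(n)
        bs = self.config.batch_size
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb, tb = X[idx], targets[idx]
            logits, activations = self._forward(xb)
            proba = _softmax(logits)
            delta = (proba - tb) / xb.shape[0]
            w_grads: List[np.ndarray] = [None] * len(self.weights)
            b_grads: List[np.ndarray] = [None] * len(self.biases)
            for layer in range(len(self.weights) - 1, -1, -1):
                w_grads[layer] = activations[layer].T @ delta
                b_grads[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ self.weights[layer].T) * (activations[layer] > 0)
            self._adam_step(w_grads + b_grads)


@dataclass
class TrainingCurves:
    """Per-epoch train/validation loss and accuracy, per repeat and averaged."""

    train_loss: np.ndarray  # (repeats, epochs)
    train_accuracy: np.ndarray
    val_loss: np.ndarray
    val_accuracy: np.ndarray

    @property
    def mean_train_loss(self) -> np.ndarray:
        return self.train_loss.mean(axis=0)

    @property
    def mean_train_accuracy(self) -> np.ndarray:
        return self.train_accuracy.mean(axis=0)

    @property
    def mean_val_loss(self) -> np.ndarray:
        return self.val_loss.mean(axis=0)

    @property
    def mean_val_accuracy(self) -> np.ndarray:
        return self.val_accuracy.mean(axis=0)


class MLPEnsemble:
    """Average-probability ensemble over the repeated trainings."""

    def __init__(self, members: List[MLP]) -> None:
        if not members:
            raise ValueError("empty ensemble")
        self.members = members
        self.classes_ = members[0].classes_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


@dataclass
class ANNResult:
    ensemble: MLPEnsemble
    curves: TrainingCurves
    metrics: MetricsReport
    per_repeat_metrics: List[MetricsReport]
    optimal_epoch: int


def train_ann(
    X_train: np.ndarray,
    y_train: Sequence[str],
    X_val: np.ndarray,
    y_val: Sequence[str],
    config: ANNConfig = ANNConfig(),
) -> ANNResult:
    """Train ``config.repeats`` independently seeded networks and average.

    Validation loss/accuracy are tracked per epoch for every repeat; the
    reported metrics are the mean of the per-repeat validation metrics, and
    the ensemble (averaged softmax) is returned for downstream ROC use.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    targets = _one_hot(y_train)
    seeds = np.random.SeedSequence(config.seed).spawn(config.repeats)

    members: List[MLP] = []
    shape = (config.repeats, config.epochs)
    train_loss = np.zeros(shape)
    train_acc = np.zeros(shape)
    val_loss = np.zeros(shape)
    val_acc = np.zeros(shape)
    for r, ss in enumerate(seeds):
        net = MLP(X_train.shape[1], config, seed=ss)
        for epoch in range(config.epochs):
            net.train_epoch(X_train, targets)
            train_loss[r, epoch], train_acc[r, epoch] = net.loss_accuracy(X_train, y_train)
            val_loss[r, epoch], val_acc[r, epoch] = net.loss_accuracy(X_val, y_val)
        members.append(net)

    curves = TrainingCurves(train_loss, train_acc, val_loss, val_acc)
    per_repeat = [evaluate_classifier(m, X_val, y_val) for m in members]
    averaged = MetricsReport(
        **{
            name: float(np.mean([getattr(m, name) for m in per_repeat]))
            if name not in ("tp", "fp", "tn", "fn")
            else int(round(np.mean([getattr(m, name) for m in per_repeat])))
            for name in (
                "accuracy",
                "specificity",
                "precision_pos",
                "precision_macro",
                "recall_pos",
                "recall_macro",
                "f1_pos",
                "f1_macro",
                "auc",
                "tp",
                "fp",
                "tn",
                "fn",
            )
        }
    )
    return ANNResult(
        ensemble=MLPEnsemble(members),
        curves=curves,
        metrics=averaged,
        per_repeat_metrics=per_repeat,
        optimal_epoch=select_optimal_epoch(curves),
    )


def select_optimal_epoch(curves: TrainingCurves) -> int:
    """1-based epoch minimizing averaged validation loss (earliest on ties)."""
    mean_val = curves.mean_val_loss
    if mean_val.size < 2:
        raise ValueError("need at least 2 epochs of validation loss")
    return int(np.argmin(mean_val)) + 1


def stratified_holdout(
    y: Sequence[str], fraction: float = 0.2, seed: int = 20241009
) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded stratified (train, holdout) index split for curve tracking."""
    from .bench import CVPlan, stratified_split

    plan = CVPlan(test_fraction=fraction, seed=seed)
    return stratified_split(y, plan)
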