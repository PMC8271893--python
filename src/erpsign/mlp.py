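"""Supervised correctness classifier: a small fully connected network.

Architecture 70-20-10-1 (ReLU hidden layers, logistic output), binary
cross-entropy loss, full-batch Adam, 500 epochs — deliberately tiny
because each group contributes only ~60 averaged traces.  Forward and
backward passes are written out explicitly so the analytic gradients can
be verified against finite differences.

4-fold stratified cross-validation with population-SD aggregation
mirrors how the classifier's accuracy is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .behavior import mean_and_popsd

__all__ = [
    "MlpConfig",
    "MlpModel",
    "CvResult",
    "train_mlp",
    "predict",
    "kfold_cv",
    "loss_and_gradients",
]

_EPS = 1e-12  # clamp for log in the cross-entropy


@dataclass
class MlpConfig:
    """Training recipe for the correctness classifier."""

    layer_sizes: tuple[int, ...] = (70, 20, 10, 1)
    epochs: int = 500
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    train_fraction: float = 0.75
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2 or self.layer_sizes[-1] != 1:
            raise ValueError("layer_sizes must end in a single output node")
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class MlpModel:
    """Trained network: per-layer weight matrices and bias vectors.

    ``feature_mean``/``feature_sd`` hold the training-set standardisation
    applied to inputs at prediction time (identity when standardisation
    is off).
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MlpConfig
    feature_mean: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.weights[0].shape[0],) + tuple(w.shape[1] for w in self.weights)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.feature_mean is not None:
            return (X - self.feature_mean) / self.feature_sd
        return X


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(weights: Sequence[np.ndarray], biases: Sequence[np.ndarray],
             X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Output probabilities and the per-layer activations (for backprop)."""
    acts = [X]
    a = X
    n_layers = len(weights)
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = a @ W + b
        a = _sigmoid(z) if i == n_layers - 1 else np.maximum(z, 0.0)
        acts.append(a)
    return a.ravel(), acts


def loss_and_gradients(weights: Sequence[np.ndarray],
                       biases: Sequence[np.ndarray],
                       X: np.ndarray, y: np.ndarray,
                       ) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Mean binary cross-entropy and its analytic gradients.

    Exposed separately from training so the backward pass can be checked
    against central finite differences.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    p, acts = _forward(weights, biases, X)
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    loss = float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))

    # output delta: d(loss)/dz for sigmoid + BCE collapses to (p - y)/n
    delta = ((p - y) / n)[:, None]
    grads_w: list[np.ndarray] = [np.empty(0)] * len(weights)
    grads_b: list[np.ndarray] = [np.empty(0)] * len(weights)
    for i in range(len(weights) - 1, -1, -1):
        grads_w[i] = acts[i].T @ delta
        grads_b[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ weights[i].T) * (acts[i] > 0)
    return loss, grads_w, grads_b


def _init_params(layer_sizes: Sequence[int], rng: np.random.Generator,
                 ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes, layer_sizes[1:]):
        # He scaling for the ReLU stack; the final layer is small anyway
        weights.append(rng.standard_normal((fan_in, fan_out))
                       * np.sqrt(2.0 / fan_in))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train_mlp(features: np.ndarray, labels: Sequence[int],
              config: MlpConfig = MlpConfig()) -> MlpModel:
    """Train the classifier with full-batch Adam; deterministic per seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features must be (n_samples, n_features) aligned "
                         "with labels")
    if X.shape[1] != config.layer_sizes[0]:
        raise ValueError(f"feature length {X.shape[1]} does not match the "
                         f"input layer ({config.layer_sizes[0]} nodes)")
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError("labels must contain both classes 0 and 1")

    mean = sd = None
    if config.standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        X = (X - mean) / sd

    rng = np.random.default_rng(config.seed)
    weights, biases = _init_params(config.layer_sizes, rng)

    # Adam state
    mw = [np.zeros_like(w) for w in weights]
    vw = [np.zeros_like(w) for w in weights]
    mb = [np.zeros_like(b) for b in biases]
    vb = [np.zeros_like(b) for b in biases]
    b1, b2, eps, lr = (config.adam_beta1, config.adam_beta2,
                       config.adam_eps, config.learning_rate)

    losses = np.empty(config.epochs)
    for epoch in range(config.epochs):
        loss, gw, gb = loss_and_gradients(weights, biases, X, y)
        losses[epoch] = loss
        t = epoch + 1
        for i in range(len(weights)):
            mw[i] = b1 * mw[i] + (1 - b1) * gw[i]
            vw[i] = b2 * vw[i] + (1 - b2) * gw[i] ** 2
            mb[i] = b1 * mb[i] + (1 - b1) * gb[i]
            vb[i] = b2 * vb[i] + (1 - b2) * gb[i] ** 2
            mhat_w = mw[i] / (1 - b1 ** t)
            vhat_w = vw[i] / (1 - b2 ** t)
            mhat_b = mb[i] / (1 - b1 ** t)
            vhat_b = vb[i] / (1 - b2 ** t)
            weights[i] = weights[i] - lr * mhat_w / (np.sqrt(vhat_w) + eps)
            biases[i] = biases[i] - lr * mhat_b / (np.sqrt(vhat_b) + eps)

    return MlpModel(weights=weights, biases=biases, config=config,
                    feature_mean=mean, feature_sd=sd, loss_history=losses)


def predict(model: MlpModel, features: np.ndarray,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels (probability >= 0.5 maps to class 1)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError(f"feature length {X.shape[1]} does not match the "
                         f"input layer ({model.layer_sizes[0]} nodes)")
    p, _ = _forward(model.weights, model.biases, model._transform(X))
    return p, (p >= 0.5).astype(int)


@dataclass(frozen=True)
class CvResult:
    """Cross-validation accuracies with mean/popsd aggregation."""

    fold_accuracies: tuple[float, ...]

    @classmethod
    def from_accuracies(cls, accuracies: Sequence[float]) -> "CvResult":
        return cls(fold_accuracies=tuple(float(a) for a in accuracies))

    @property
    def mean(self) -> float:
        return mean_and_popsd(self.fold_accuracies)[0]

    @property
    def popsd(self) -> float:
        return mean_and_popsd(self.fold_accuracies)[1]


def kfold_cv(features: np.ndarray, labels: Sequence[int], k: int = 4,
             config: MlpConfig = MlpConfig(), seed: int = 0) -> CvResult:
    """Stratified k-fold cross-validation of the classifier.

    Fold assignment is stratified with seeded shuffling; each rotation
    trains on k-1 folds (with a fold-specific training seed) and scores
    accuracy on the held-out fold.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int).ravel()
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} samples")
    _, counts = np.unique(y, return_counts=True)
    if counts.size < 2 or counts.min() < k:
        raise ValueError("every fold needs both classes: each class must "
                         f"have at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        fold_cfg = MlpConfig(**{**config.__dict__, "seed": config.seed + fold})
        model = train_mlp(X[train_idx], y[train_idx], fold_cfg)
        _, pred = predict(model, X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
    return CvResult.from_accuracies(accs)
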