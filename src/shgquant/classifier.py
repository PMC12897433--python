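"""Single-sigmoid-neuron binary fibrosis classifier with k-fold CV.

The model is one sigmoid unit, p = sigmoid(w.x + b), trained full-batch
with the Adam optimizer (learning rate 0.05, beta1=0.9, beta2=0.999,
eps=1e-8) on the binary cross-entropy loss

    L = -(1/n) sum_i [ y_i log p_i + (1 - y_i) log(1 - p_i) ].

The default input is the single image-level above-threshold pixel fraction
(frac_above), which is linearly separable between the fibrotic and
non-fibrotic classes under the default phantom conditions, so a linear
decision boundary suffices. Hard labels use the strict rule p > 0.5.

Generalization is estimated with stratified 20-fold cross-validation whose
per-fold confusion matrices are summed into one aggregate matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

#: Clipping bound applied to probabilities inside the loss (never prediction).
EPS_CLIP = 1e-12


@dataclass
class NeuronModel:
    """Trained weights plus the training-split standardization constants."""

    w: np.ndarray
    b: float
    feature_mean: np.ndarray
    feature_std: np.ndarray
    lr: float = 0.05
    epochs: int = 500
    loss_history: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class CVReport:
    """Per-fold and aggregated confusion matrices with summary metrics."""

    fold_matrices: list[ConfusionMatrix]
    aggregate: ConfusionMatrix
    f1: float
    sensitivity: float
    specificity: float
    accuracy: float
    k: int
    seed: int


def bce_loss(labels: np.ndarray, probabilities: np.ndarray,
             eps_clip: float = EPS_CLIP) -> float:
    """Mean binary cross-entropy with probability clipping."""
    y = np.asarray(labels, dtype=float)
    p = np.asarray(probabilities, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    p = np.clip(p, eps_clip, 1.0 - eps_clip)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _as_2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[:, None] if X.ndim == 1 else X


def train_neuron(X: np.ndarray, y: np.ndarray, lr: float = 0.05,
                 epochs: int = 500, standardize: bool = True) -> NeuronModel:
    """Fit the sigmoid neuron by full-batch Adam on the BCE loss.

    Features are standardized with the training-split mean and SD (stored
    on the model); weights start at zero, so training is deterministic
    given the data ordering.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training split must contain both classes")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if standardize:
        if np.any(sd == 0):
            allzero = np.allclose(X, X[0])
            if allzero and X.shape[1] == 1:
                # degenerate constant feature: keep raw scale (zero gradient
                # symmetry case); caller sees p = 0.5 everywhere
                mu = np.zeros_like(mu)
                sd = np.ones_like(sd)
            else:
                raise ValueError("zero-variance feature in training split")
    else:
        mu = np.zeros_like(mu)
        sd = np.ones_like(sd)
    Xs = (X - mu) / sd

    n, d = Xs.shape
    w = np.zeros(d)
    b = 0.0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = np.zeros(d + 1)
    v = np.zeros(d + 1)
    losses = np.empty(epochs)
    for t in range(1, epochs + 1):
        p = expit(Xs @ w + b)
        losses[t - 1] = bce_loss(y, p)
        gz = (p - y) / n
        grad = np.concatenate([Xs.T @ gz, [gz.sum()]])
        m = beta1 * m + (1 - beta1) * grad
        v = beta2 * v + (1 - beta2) * grad**2
        mhat = m / (1 - beta1**t)
        vhat = v / (1 - beta2**t)
        step = lr * mhat / (np.sqrt(vhat) + eps)
        w -= step[:d]
        b -= float(step[d])

    tail = losses[-max(1, epochs // 10):]
    if np.any(np.diff(tail) > 1e-6):
        logger.info("training loss not monotone over the final 10%% of epochs "
                    "(last=%.4g)", losses[-1])
    return NeuronModel(w=w, b=b, feature_mean=mu, feature_std=sd, lr=lr,
                       epochs=epochs, loss_history=losses)


def predict(model: NeuronModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities and hard labels (1 iff p > 0.5, strictly)."""
    X = _as_2d(X)
    if X.shape[1] != model.w.size:
        raise ValueError(
            f"feature dimensionality {X.shape[1]} != model's {model.w.size}")
    Xs = (X - model.feature_mean) / model.feature_std
    p = expit(Xs @ model.w + model.b)
    return p, (p > 0.5).astype(int)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def confusion_metrics(matrix: ConfusionMatrix) -> dict[str, float]:
    """F1, sensitivity, specificity, accuracy from one confusion matrix.

    Undefined ratios (zero denominators) raise with an explanation rather
    than returning NaN.
    """
    tp, fp, tn, fn = matrix.tp, matrix.fp, matrix.tn, matrix.fn
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if matrix.total == 0:
        raise ValueError("confusion matrix is empty")
    if tp + fn == 0:
        raise ValueError("sensitivity undefined: no positive samples (TP+FN=0)")
    if tn + fp == 0:
        raise ValueError("specificity undefined: no negative samples (TN+FP=0)")
    return {
        "f1": 2 * tp / (2 * tp + fp + fn),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "accuracy": (tp + tn) / matrix.total,
    }


def _stratified_folds(y: np.ndarray, k: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = rng.permutation(np.flatnonzero(y == cls))
        for f, chunk in enumerate(np.array_split(idx, k)):
            folds[f].extend(chunk.tolist())
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def _plain_folds(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(idx, k)]


def kfold_cv(X: np.ndarray, y: np.ndarray, k: int = 20, seed: int = 0,
             stratified: bool = True, lr: float = 0.05,
             epochs: int = 500) -> CVReport:
    """Stratified k-fold cross-validation with an aggregated confusion matrix.

    Each sample is validated exactly once; per-fold matrices are summed
    element-wise and the metrics are computed from the aggregate.
    """
    X = _as_2d(X)
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < k:
        raise ValueError(f"need at least k={k} samples")
    if stratified:
        counts = np.bincount(y, minlength=2)
        if counts.min() < k:
            raise ValueError("every class needs >= k members for "
                             "stratified folds")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng) if stratified else _plain_folds(n, k, rng)

    fold_matrices: list[ConfusionMatrix] = []
    aggregate = ConfusionMatrix()
    for val_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[val_idx] = False
        if np.unique(y[train_mask]).size < 2:
            raise ValueError("a training split lost one class entirely")
        model = train_neuron(X[train_mask], y[train_mask], lr=lr, epochs=epochs)
        _, pred = predict(model, X[val_idx])
        cm = confusion_counts(y[val_idx], pred)
        fold_matrices.append(cm)
        aggregate = aggregate + cm
    assert aggregate.total == n
    metrics = confusion_metrics(aggregate)
    return CVReport(fold_matrices=fold_matrices, aggregate=aggregate,
                    f1=metrics["f1"], sensitivity=metrics["sensitivity"],
                    specificity=metrics["specificity"],
                    accuracy=metrics["accuracy"], k=k, seed=seed)
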