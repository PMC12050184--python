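"""Three-layer sigmoid network over SSM mode coefficients.

Architecture: input (t mode coefficients, standardized by sqrt(lambda_k)),
one sigmoid hidden layer, and one sigmoid output unit per class:

    H = sigmoid(W' phi + B),   P = sigmoid(V' H + C).

The outputs are independent sigmoids, NOT a softmax: each class gets its
own score in (0, 1) so a per-class ROC threshold (e.g. "normal if
P > 0.333") is meaningful.  The matching loss is the per-class binary
cross-entropy summed over classes and samples; the plain multi-label
cross-entropy  -sum L_i log P_i  is available via ``loss_kind='ce'``.
Training is per-sample stochastic gradient descent with hand-derived
backpropagation — the model is small enough that no autodiff framework is
warranted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

DEFAULT_CLASSES = ("normal", "barton", "colles", "smith")
_CLIP = 1e-12


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


@dataclass
class ClassifierModel:
    W: np.ndarray                       # (t, hidden)
    B: np.ndarray                       # (hidden,)
    V: np.ndarray                       # (hidden, n_classes)
    C: np.ndarray                       # (n_classes,)
    classes: tuple = DEFAULT_CLASSES
    feature_scale: Optional[np.ndarray] = None   # per-feature divisor sqrt(lambda)
    thresholds: Optional[np.ndarray] = None      # per-class decision cutoffs

    def __post_init__(self):
        for name in "WBVC":
            setattr(self, name, np.asarray(getattr(self, name), np.float64))
        t, h = self.W.shape
        c = len(self.classes)
        if self.B.shape != (h,) or self.V.shape != (h, c) or self.C.shape != (c,):
            raise ValidationError("inconsistent weight dimensions")
        if self.feature_scale is not None:
            self.feature_scale = np.asarray(self.feature_scale, np.float64)
            if self.feature_scale.shape != (t,):
                raise ValidationError("feature_scale length != feature count")
            if np.any(self.feature_scale <= 0):
                raise ValidationError("feature_scale entries must be positive")
        if self.thresholds is not None:
            self.thresholds = np.asarray(self.thresholds, np.float64)
            if self.thresholds.shape != (c,):
                raise ValidationError("one threshold per class required")
            if np.any((self.thresholds <= 0) | (self.thresholds >= 1)):
                raise ValidationError("thresholds must lie in (0, 1)")

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "ClassifierModel":
        return replace(self, W=self.W.copy(), B=self.B.copy(),
                       V=self.V.copy(), C=self.C.copy())


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    max_epochs: int = 2000
    batch_size: int = 1
    tol: float = 1e-6
    seed: int = 0
    loss_kind: str = "bce"

    def __post_init__(self):
        if self.learning_rate <= 0 or self.max_epochs < 0 or self.batch_size < 1:
            raise ValidationError("invalid training configuration")
        if self.loss_kind not in ("bce", "ce"):
            raise ValidationError("loss_kind must be 'bce' or 'ce'")


def init_classifier(t: int, hidden_size: int = 10,
                    classes: Sequence[str] = DEFAULT_CLASSES,
                    seed: int = 0,
                    feature_scale: Optional[np.ndarray] = None
                    ) -> ClassifierModel:
    """Glorot-uniform weights, zero biases, reproducible per seed."""
    if t < 1 or hidden_size < 1 or len(classes) < 2:
        raise ValidationError("sizes must be positive (>= 2 classes)")
    rng = np.random.default_rng(seed)
    lim_w = np.sqrt(6.0 / (t + hidden_size))
    lim_v = np.sqrt(6.0 / (hidden_size + len(classes)))
    return ClassifierModel(
        W=rng.uniform(-lim_w, lim_w, (t, hidden_size)),
        B=np.zeros(hidden_size),
        V=rng.uniform(-lim_v, lim_v, (hidden_size, len(classes))),
        C=np.zeros(len(classes)),
        classes=tuple(classes),
        feature_scale=feature_scale)


def forward(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Class scores in (0, 1); accepts a single feature vector or a batch."""
    x = np.asarray(features, dtype=np.float64)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.n_features:
        raise ValidationError(
            f"expected {model.n_features} features, got {x.shape[1]}")
    h = sigmoid(x @ model.W + model.B)
    p = sigmoid(h @ model.V + model.C)
    return p[0] if single else p


def _check_one_hot(labels):
    y = np.atleast_2d(np.asarray(labels, dtype=np.float64))
    if not (np.all((y == 0) | (y == 1)) and np.all(y.sum(axis=1) == 1)):
        raise ValidationError("labels must be one-hot rows")
    return y


def loss(labels: np.ndarray, probs: np.ndarray, kind: str = "bce") -> float:
    """Cross-entropy summed over samples and classes.

    'bce' adds the complement term -sum (1-L) log(1-P) appropriate for
    independent sigmoid outputs; 'ce' is the plain -sum L log P.
    """
    y = _check_one_hot(labels)
    p = np.clip(np.atleast_2d(np.asarray(probs, np.float64)), _CLIP, 1 - _CLIP)
    if y.shape != p.shape:
        raise ValidationError("labels/probs shape mismatch")
    total = -np.sum(y * np.log(p))
    if kind == "bce":
        total -= np.sum((1 - y) * np.log(1 - p))
    elif kind != "ce":
        raise ValidationError("kind must be 'bce' or 'ce'")
    return float(total)


def loss_and_gradients(model: ClassifierModel, x: np.ndarray, y: np.ndarray,
                       kind: str = "bce"):
    """Loss and analytic gradients for a (mini)batch.

    Returns ``(loss_value, dict with dW, dB, dV, dC)``.
    """
    x = np.atleast_2d(np.asarray(x, np.float64))
    y = _check_one_hot(y)
    h = sigmoid(x @ model.W + model.B)
    z_out = h @ model.V + model.C
    p = sigmoid(z_out)
    value = loss(y, p, kind=kind)
    pc = np.clip(p, _CLIP, 1 - _CLIP)
    if kind == "bce":
        # d/dz of sum BCE over independent sigmoids
        delta_out = pc - y
    else:
        delta_out = -y * (1.0 - pc)
    d_v = h.T @ delta_out
    d_c = delta_out.sum(axis=0)
    delta_hid = (delta_out @ model.V.T) * h * (1.0 - h)
    d_w = x.T @ delta_hid
    d_b = delta_hid.sum(axis=0)
    return value, {"dW": d_w, "dB": d_b, "dV": d_v, "dC": d_c}


def train_sgd(model: ClassifierModel, features: np.ndarray, labels: np.ndarray,
              config: TrainConfig | None = None):
    """Stochastic gradient descent over shuffled per-sample (or minibatch)
    updates.  Stops at ``max_epochs`` or when the epoch-mean loss changes by
    less than ``tol``.  Returns ``(trained model, per-epoch loss history)``.
    """
    config = config or TrainConfig()
    x = np.atleast_2d(np.asarray(features, np.float64))
    y = _check_one_hot(labels)
    if len(x) != len(y):
        raise ValidationError("features/labels length mismatch")
    if len(x) < len(model.classes):
        raise ValidationError("need at least one sample per class")
    if y.shape[1] != len(model.classes):
        raise ValidationError("label width != class count")
    present = y.sum(axis=0) > 0
    if not np.all(present):
        missing = [c for c, ok in zip(model.classes, present) if not ok]
        raise ValidationError(f"classes absent from training data: {missing}")
    out = model.copy()
    rng = np.random.default_rng(config.seed)
    lr = config.learning_rate
    history = []
    prev = None
    for _ in range(config.max_epochs):
        order = rng.permutation(len(x))
        for start in range(0, len(x), config.batch_size):
            sel = order[start:start + config.batch_size]
            value, g = loss_and_gradients(out, x[sel], y[sel], config.loss_kind)
            if not np.isfinite(value):
                raise ValidationError(
                    "training loss became non-finite — lower the learning "
                    f"rate (currently {lr})")
            out.W -= lr * g["dW"]
            out.B -= lr * g["dB"]
            out.V -= lr * g["dV"]
            out.C -= lr * g["dC"]
        if not all(np.all(np.isfinite(a))
                   for a in (out.W, out.B, out.V, out.C)):
            raise ValidationError(
                "weights diverged to non-finite values — lower the learning "
                f"rate (currently {lr})")
        epoch_loss = loss(y, forward(out, x), kind=config.loss_kind) / len(x)
        history.append(epoch_loss)
        if prev is not None and abs(prev - epoch_loss) < config.tol:
            break
        prev = epoch_loss
    return out, history


def predict(model: ClassifierModel, features: np.ndarray,
            use_thresholds: bool = False):
    """Predict labels for one or many feature vectors.

    Returns ``(labels, per-class binary decisions, probabilities)``.  The
    single label is the argmax class (ties -> first class in declared
    order); binary decisions compare each class score against its own
    threshold and may disagree with the argmax label.
    """
    p = forward(model, features)
    single = p.ndim == 1
    p2 = np.atleast_2d(p)
    if use_thresholds:
        if model.thresholds is None:
            raise ValidationError("model has no per-class thresholds set")
        decisions = p2 > model.thresholds
    else:
        decisions = None
    win = np.argmax(p2, axis=1)   # argmax returns the first maximal index
    labels = [model.classes[i] for i in win]
    if single:
        return labels[0], (None if decisions is None else decisions[0]), p
    return labels, decisions, p2


def one_hot(labels: Sequence[str], classes: Sequence[str] = DEFAULT_CLASSES
            ) -> np.ndarray:
    classes = list(classes)
    y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        if lab not in classes:
            raise ValidationError(f"unknown label {lab!r}")
        y[i, classes.index(lab)] = 1.0
    return y
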