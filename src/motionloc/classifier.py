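"""Multi-layer perceptron classifier.

Architecture: three ReLU hidden layers of 64, 64 and 32 units feeding a
softmax output, trained by plain stochastic gradient descent (no momentum) on
the categorical cross-entropy, with early stopping on a stratified validation
split: training halts when the validation loss has not improved by at least
``min_improvement`` for ``patience`` consecutive epochs, and the
best-validation weights are restored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import FeatureMatrix
from .errors import SchemaError, TrainingError, ValidationError


@dataclass(frozen=True)
class MlpConfig:
    hidden_sizes: tuple[int, ...] = (64, 64, 32)
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.2
    learning_rate: float = 0.01
    min_improvement: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValidationError("hidden layer sizes must be positive")
        if not 0 < self.validation_fraction < 1:
            raise ValidationError("validation fraction must be in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValidationError("patience cannot exceed max_epochs")
        if self.learning_rate <= 0:
            raise ValidationError("learning rate must be > 0")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _cross_entropy(proba: np.ndarray, y_idx: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(proba[np.arange(len(y_idx)), y_idx] + eps)))


@dataclass
class TrainedClassifier:
    """Fitted MLP weights plus the training-time feature/class bookkeeping."""

    feature_names: list[str]
    class_names: list[str]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: MlpConfig
    best_validation_loss: float = float("nan")
    final_validation_loss: float = float("nan")
    n_epochs: int = 0
    refinery_state_ref: str | None = None

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        return _softmax(h @ self.weights[-1] + self.biases[-1])

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "class_names": self.class_names,
                "weights": [w.tolist() for w in self.weights],
                "biases": [b.tolist() for b in self.biases],
                "config": {
                    "hidden_sizes": list(self.config.hidden_sizes),
                    "batch_size": self.config.batch_size,
                    "max_epochs": self.config.max_epochs,
                    "patience": self.config.patience,
                    "validation_fraction": self.config.validation_fraction,
                    "learning_rate": self.config.learning_rate,
                    "min_improvement": self.config.min_improvement,
                    "seed": self.config.seed,
                },
                "best_validation_loss": self.best_validation_loss,
                "final_validation_loss": self.final_validation_loss,
                "n_epochs": self.n_epochs,
                "refinery_state_ref": self.refinery_state_ref,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedClassifier":
        d = json.loads(text)
        cfg = dict(d["config"])
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        return cls(
            feature_names=list(d["feature_names"]),
            class_names=list(d["class_names"]),
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            config=MlpConfig(**cfg),
            best_validation_loss=float(d["best_validation_loss"]),
            final_validation_loss=float(d["final_validation_loss"]),
            n_epochs=int(d["n_epochs"]),
            refinery_state_ref=d.get("refinery_state_ref"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        return cls.from_json(Path(path).read_text())


def _check_features(model: TrainedClassifier, features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        if features.feature_names != model.feature_names:
            raise SchemaError(
                "feature names/order do not match the training matrix"
            )
        x = features.rows
    else:
        x = np.asarray(features, dtype=float)
        x = x.reshape(-1, len(model.feature_names)) if x.size else x.reshape(0, len(model.feature_names))
        if x.shape[1] != len(model.feature_names):
            raise SchemaError(
                f"expected {len(model.feature_names)} columns, got {x.shape[1]}"
            )
    return x


def _stratified_split(
    y_idx: np.ndarray, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, val_idx = [], []
    for cls in np.unique(y_idx):
        members = np.flatnonzero(y_idx == cls)
        members = rng.permutation(members)
        n_val = max(1, int(round(fraction * len(members))))
        if n_val >= len(members):
            n_val = len(members) - 1
        val_idx.append(members[:n_val])
        train_idx.append(members[n_val:])
    return np.concatenate(train_idx), np.concatenate(val_idx)


def train(features: FeatureMatrix, cfg: MlpConfig | None = None) -> TrainedClassifier:
    """Fit the MLP on a feature matrix; deterministic for a fixed seed."""
    cfg = cfg or MlpConfig()
    x = features.rows
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite feature values")
    class_names = sorted(set(features.labels))
    if len(class_names) < 2:
        raise TrainingError("training needs at least 2 classes")
    if len(features.labels) < 10 * len(class_names):
        raise TrainingError(
            f"need at least {10 * len(class_names)} rows for {len(class_names)} classes"
        )
    class_idx = {c: i for i, c in enumerate(class_names)}
    y = np.array([class_idx[l] for l in features.labels])
    n_classes = len(class_names)
    n_features = x.shape[1]

    rng = np.random.default_rng(cfg.seed)
    sizes = [n_features, *cfg.hidden_sizes, n_classes]
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))

    tr, va = _stratified_split(y, cfg.validation_fraction, rng)
    x_tr, y_tr, x_va, y_va = x[tr], y[tr], x[va], y[va]

    def forward_cache(xb):
        acts = [xb]
        h = xb
        for w, b in zip(weights[:-1], biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
            acts.append(h)
        proba = _softmax(h @ weights[-1] + biases[-1])
        return acts, proba

    def val_loss() -> float:
        _, proba = forward_cache(x_va)
        return _cross_entropy(proba, y_va)

    best_loss = np.inf  # tracks weight restoration (any strict improvement)
    patience_ref = np.inf  # tracks early stopping (improvement >= min_improvement)
    best_weights = [w.copy() for w in weights]
    best_biases = [b.copy() for b in biases]
    wait = 0
    epochs_run = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, yb = x_tr[batch], y_tr[batch]
            acts, proba = forward_cache(xb)
            delta = proba
            delta[np.arange(len(yb)), yb] -= 1.0
            delta /= len(yb)
            for layer in range(len(weights) - 1, -1, -1):
                grad_w = acts[layer].T @ delta
                grad_b = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * (acts[layer] > 0.0)
                weights[layer] -= cfg.learning_rate * grad_w
                biases[layer] -= cfg.learning_rate * grad_b
        epochs_run = epoch + 1
        loss = val_loss()
        if loss < best_loss:
            best_loss = loss
            best_weights = [w.copy() for w in weights]
            best_biases = [b.copy() for b in biases]
        if patience_ref - loss >= cfg.min_improvement:
            patience_ref = loss
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break
    final_loss = val_loss()

    return TrainedClassifier(
        feature_names=list(features.feature_names),
        class_names=class_names,
        weights=best_weights,
        biases=best_biases,
        config=cfg,
        best_validation_loss=float(best_loss if np.isfinite(best_loss) else final_loss),
        final_validation_loss=float(final_loss),
        n_epochs=epochs_run,
    )


def predict_proba(model: TrainedClassifier, features) -> np.ndarray:
    """Class-probability matrix; rows are non-negative and sum to 1."""
    x = _check_features(model, features)
    if x.shape[0] == 0:
        return np.empty((0, len(model.class_names)))
    return model._forward(x)


def predict(model: TrainedClassifier, features) -> list[str]:
    """Argmax of predict_proba with a lowest-index tie-break."""
    proba = predict_proba(model, features)
    return [model.class_names[i] for i in np.argmax(proba, axis=1)]
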