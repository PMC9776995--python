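"""Three-class classifiers over the 6-value feature vectors.

The final deployed classifier is histogram gradient boosting; the comparison
suite additionally offers plain gradient boosting, random forest, decision
tree, Gaussian naive Bayes and a feed-forward neural network (trained by an
iterative optimizer with early stopping, max 3000 iterations).
"""

from __future__ import annotations

import pickle
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .errors import ContractError
from .io_formats import CLASS_ORDER, FeatureRow

ALGORITHMS = (
    "hist_gradient_boosting",
    "gradient_boosting",
    "random_forest",
    "decision_tree",
    "naive_bayes",
    "neural_net",
)

DEFAULT_ALGORITHM = "hist_gradient_boosting"

_MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Training configuration; unspecified hyperparameters stay at library defaults."""

    algorithm: str = DEFAULT_ALGORITHM
    max_iterations: int = 3000
    early_stopping: bool = True
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ContractError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}"
            )
        if self.max_iterations < 1:
            raise ContractError("max_iterations must be >= 1")
        if not 0.0 < self.validation_fraction <= 0.5:
            raise ContractError("validation_fraction must be in (0, 0.5]")


@dataclass
class TrainedModel:
    """A fitted classifier with its fixed class order and training history."""

    algorithm: str
    classes: tuple[str, str, str]
    estimator: object
    seed: int
    training_history: Optional[list[tuple[float, float]]] = None


def _component_seed(seed: int, component: str) -> int:
    """Derive a stable per-component seed from the single pipeline seed."""
    return (seed * 1000003 + zlib.crc32(component.encode())) % (2**31)


def _make_estimator(config: TrainConfig):
    seed = _component_seed(config.seed, config.algorithm)
    if config.algorithm == "hist_gradient_boosting":
        # 'auto' enables early stopping only when the data are large enough
        # for a stratified validation split to make sense
        return HistGradientBoostingClassifier(
            random_state=seed,
            early_stopping="auto" if config.early_stopping else False,
            validation_fraction=config.validation_fraction,
        )
    if config.algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if config.algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if config.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if config.algorithm == "naive_bayes":
        return GaussianNB()
    if config.algorithm == "neural_net":
        # moment features span many orders of magnitude; the network needs
        # standardized inputs to train at all
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                random_state=seed,
                max_iter=config.max_iterations,
                early_stopping=config.early_stopping,
                validation_fraction=config.validation_fraction,
                # default patience (10) stops before the optimizer leaves its
                # initial plateau on small standardized datasets
                n_iter_no_change=30,
            ),
        )
    raise ContractError(f"unknown algorithm {config.algorithm!r}")


def _feature_matrix(rows: Sequence[FeatureRow]) -> np.ndarray:
    X = np.asarray([r.features for r in rows], dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != 6:
        raise ContractError("every feature row must carry exactly 6 values")
    return X


def _history(estimator) -> Optional[list[tuple[float, float]]]:
    """Per-iteration (train_loss, validation_loss) pairs, when the fitted
    estimator exposes them."""
    if isinstance(estimator, Pipeline):
        estimator = estimator[-1]
    if isinstance(estimator, HistGradientBoostingClassifier):
        train = getattr(estimator, "train_score_", None)
        val = getattr(estimator, "validation_score_", None)
        if train is not None and val is not None:
            return [(-t, -v) for t, v in zip(train, val)]
        if train is not None:
            return [(-t, -t) for t in train]
    if isinstance(estimator, MLPClassifier):
        train = getattr(estimator, "loss_curve_", None)
        val = getattr(estimator, "validation_scores_", None)
        if train is not None and val is not None:
            return [(t, 1.0 - v) for t, v in zip(train, val)]
        if train is not None:
            return [(t, t) for t in train]
    return None


def _fit(rows: list[FeatureRow], config: TrainConfig) -> TrainedModel:
    """Fit without the public size/class checks (used for per-fold models,
    whose training sets may legitimately be tiny or single-class)."""
    labels = [r.class_label for r in rows]
    if any(lbl is None for lbl in labels):
        raise ContractError("all training rows must be labeled")
    X = _feature_matrix(rows)
    estimator = _make_estimator(config)
    estimator.fit(X, np.asarray(labels))
    return TrainedModel(
        algorithm=config.algorithm,
        classes=CLASS_ORDER,
        estimator=estimator,
        seed=config.seed,
        training_history=_history(estimator),
    )


def train(features: Sequence[FeatureRow], config: TrainConfig | None = None) -> TrainedModel:
    """Fit the configured classifier on labeled feature rows.

    Same (data, config, seed) always yields a model with identical
    predictions.
    """
    config = config or TrainConfig()
    rows = list(features)
    if len(rows) < 5:
        raise ContractError(f"need at least 5 training samples, got {len(rows)}")
    labels = {r.class_label for r in rows}
    if len(labels) < 2:
        raise ContractError("training data must contain at least 2 classes")
    return _fit(rows, config)


def predict(model: TrainedModel, features: Sequence[FeatureRow]) -> list[str]:
    """Predict one class label (from ``model.classes``) per feature row."""
    X = _feature_matrix(list(features))
    return [str(lbl) for lbl in model.estimator.predict(X)]


def predict_proba(model: TrainedModel, features: Sequence[FeatureRow]) -> np.ndarray:
    """Per-sample probability triples, columns in ``model.classes`` order.

    Classes absent from training get probability 0, so rows still sum to 1.
    """
    X = _feature_matrix(list(features))
    raw = model.estimator.predict_proba(X)
    fitted = [str(c) for c in model.estimator.classes_]
    out = np.zeros((len(X), len(model.classes)), dtype=np.float64)
    for j, cls in enumerate(model.classes):
        if cls in fitted:
            out[:, j] = raw[:, fitted.index(cls)]
    return out


def save_model(model: TrainedModel, path: str) -> None:
    """Serialize a fitted model with a format-version header."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "algorithm": model.algorithm,
        "classes": model.classes,
        "seed": model.seed,
        "estimator": model.estimator,
        "training_history": model.training_history,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ContractError(f"unsupported model format version {version!r}")
    return TrainedModel(
        algorithm=payload["algorithm"],
        classes=tuple(payload["classes"]),
        estimator=payload["estimator"],
        seed=payload["seed"],
        training_history=payload["training_history"],
    )
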