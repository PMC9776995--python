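"""Validation protocols and metrics for the three-class problem.

Each class is scored one-vs-rest (the other two classes pooled as
negatives), yielding per-class specificity, sensitivity, accuracy and
Matthews correlation.  Four protocols are provided: self-consistency,
stratified k-fold cross-validation (pooled out-of-fold scoring), jackknife
(leave-one-out) and an independent stratified train/test split.

Conventions: any metric with a zero denominator is reported as 0; the
aggregate "accuracy" is the plain multiclass fraction correct while
aggregate specificity/sensitivity/MCC are unweighted means over the three
one-vs-rest values; CV/jackknife predictions are pooled and scored once.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_curve

from .dataset_builder import stratified_split
from .errors import ContractError
from .io_formats import CLASS_ORDER, FeatureRow
from .model import TrainConfig, TrainedModel, _fit, predict, predict_proba, train

ROC_GRID_POINTS = 101  # fixed FPR grid for vertical averaging of fold ROCs


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ContractError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    specificity: float
    sensitivity: float
    accuracy: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "accuracy": self.accuracy,
            "mcc": self.mcc,
        }


@dataclass
class EvaluationReport:
    """Everything one validation run produces, JSON-serializable."""

    protocol: str
    per_class: dict[str, MetricSet]
    macro: MetricSet
    roc: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    per_fold_accuracy: Optional[list[float]] = None
    mean_roc: Optional[dict[str, dict[str, list[float]]]] = None
    config: Optional[dict] = None
    predictions: Optional[list[str]] = None  # pooled, in dataset order

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "per_class": {c: m.as_dict() for c, m in self.per_class.items()},
            "macro": self.macro.as_dict(),
            "roc": self.roc,
            "per_fold_accuracy": self.per_fold_accuracy,
            "mean_roc": self.mean_roc,
            "config": self.config,
            "predictions": self.predictions,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            protocol=d["protocol"],
            per_class={c: MetricSet(**m) for c, m in d["per_class"].items()},
            macro=MetricSet(**d["macro"]),
            roc=d.get("roc", {}),
            per_fold_accuracy=d.get("per_fold_accuracy"),
            mean_roc=d.get("mean_roc"),
            config=d.get("config"),
            predictions=d.get("predictions"),
        )


def ovr_counts(
    y_true: Sequence[str], y_pred: Sequence[str], positive_class: str
) -> ConfusionCounts:
    """One-vs-rest confusion counts for ``positive_class``."""
    if len(y_true) != len(y_pred):
        raise ContractError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def binary_metrics(c: ConfusionCounts) -> MetricSet:
    """Specificity, sensitivity, accuracy and MCC from one confusion table."""
    if c.total == 0:
        raise ContractError("cannot compute metrics over zero samples")
    mcc_den_sq = (c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    return MetricSet(
        specificity=_safe_div(c.TN, c.TN + c.FP),
        sensitivity=_safe_div(c.TP, c.TP + c.FN),
        accuracy=(c.TP + c.TN) / c.total,
        mcc=_safe_div(c.TP * c.TN - c.FP * c.FN, math.sqrt(mcc_den_sq)),
    )


def _roc_for_class(
    y_true: Sequence[str], scores: np.ndarray, cls: str
) -> dict[str, list[float]]:
    col = CLASS_ORDER.index(cls)
    y_bin = np.asarray([1 if t == cls else 0 for t in y_true])
    if y_bin.sum() == 0 or y_bin.sum() == len(y_bin):
        # degenerate: class absent (or exclusive); ROC undefined, report diagonal
        return {"fpr": [0.0, 1.0], "tpr": [0.0, 1.0], "auc": 0.5}
    fpr, tpr, _ = roc_curve(y_bin, scores[:, col])
    auc = float(np.trapezoid(tpr, fpr))
    return {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": auc}


def evaluate_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    scores: Optional[np.ndarray] = None,
    protocol: str = "custom",
) -> EvaluationReport:
    """Score aligned true/predicted labels (plus optional probabilities)."""
    if len(y_true) != len(y_pred):
        raise ContractError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    per_class = {c: binary_metrics(ovr_counts(y_true, y_pred, c)) for c in CLASS_ORDER}
    correct = sum(1 for t, p in zip(y_true, y_pred) if t == p)
    macro = MetricSet(
        specificity=float(np.mean([m.specificity for m in per_class.values()])),
        sensitivity=float(np.mean([m.sensitivity for m in per_class.values()])),
        accuracy=correct / len(y_true),
        mcc=float(np.mean([m.mcc for m in per_class.values()])),
    )
    roc: dict[str, dict[str, list[float]]] = {}
    if scores is not None:
        scores = np.asarray(scores, dtype=np.float64)
        if scores.shape != (len(y_true), len(CLASS_ORDER)):
            raise ContractError(f"scores must have shape (n, 3), got {scores.shape}")
        roc = {c: _roc_for_class(y_true, scores, c) for c in CLASS_ORDER}
    return EvaluationReport(protocol=protocol, per_class=per_class, macro=macro, roc=roc)


def self_consistency(
    dataset: Sequence[FeatureRow], config: TrainConfig | None = None
) -> EvaluationReport:
    """Train on all samples and score predictions on those same samples."""
    rows = list(dataset)
    model = train(rows, config)
    y_true = [r.class_label for r in rows]
    y_pred = predict(model, rows)
    report = evaluate_predictions(
        y_true, y_pred, predict_proba(model, rows), protocol="self_consistency"
    )
    report.predictions = y_pred
    return report


def _fold_assignment(rows: list[FeatureRow], k: int, seed: int) -> np.ndarray:
    """Stratified fold ids: seeded shuffle within class, then round-robin
    over the class-blocked order so per-class and global fold sizes differ
    by at most 1."""
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, r in enumerate(rows):
        by_class.setdefault(r.class_label, []).append(i)
    folds = np.empty(len(rows), dtype=np.int64)
    position = 0
    for cls in sorted(by_class):
        members = np.asarray(by_class[cls])
        rng.shuffle(members)
        for idx in members:
            folds[idx] = position % k
            position += 1
    return folds


def _out_of_fold(
    rows: list[FeatureRow], folds: np.ndarray, k: int, config: TrainConfig
) -> tuple[list[str], np.ndarray, list[float]]:
    """Train k models, predict each held-out fold once, pool the results."""
    n = len(rows)
    y_pred: list[Optional[str]] = [None] * n
    scores = np.zeros((n, len(CLASS_ORDER)))
    fold_acc: list[float] = []
    for f in range(k):
        test_idx = [i for i in range(n) if folds[i] == f]
        train_idx = [i for i in range(n) if folds[i] != f]
        if not test_idx:
            continue
        model = _fit([rows[i] for i in train_idx], config)
        held = [rows[i] for i in test_idx]
        preds = predict(model, held)
        probs = predict_proba(model, held)
        for j, i in enumerate(test_idx):
            y_pred[i] = preds[j]
            scores[i] = probs[j]
        fold_acc.append(
            sum(1 for j, i in enumerate(test_idx) if preds[j] == rows[i].class_label)
            / len(test_idx)
        )
    assert all(p is not None for p in y_pred)
    return [str(p) for p in y_pred], scores, fold_acc


def _vertical_mean_roc(
    rows: list[FeatureRow], folds: np.ndarray, k: int, y_scores: np.ndarray
) -> dict[str, dict[str, list[float]]]:
    """Mean ROC over folds: per-fold TPR interpolated on a fixed FPR grid."""
    grid = np.linspace(0.0, 1.0, ROC_GRID_POINTS)
    out: dict[str, dict[str, list[float]]] = {}
    for cls in CLASS_ORDER:
        col = CLASS_ORDER.index(cls)
        tprs = []
        for f in range(k):
            idx = [i for i in range(len(rows)) if folds[i] == f]
            y_bin = np.asarray([1 if rows[i].class_label == cls else 0 for i in idx])
            if len(idx) == 0 or y_bin.sum() in (0, len(y_bin)):
                continue
            fpr, tpr, _ = roc_curve(y_bin, y_scores[idx, col])
            tprs.append(np.interp(grid, fpr, tpr))
        if tprs:
            mean_tpr = np.mean(tprs, axis=0)
            mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
            out[cls] = {
                "fpr": grid.tolist(),
                "tpr": mean_tpr.tolist(),
                "auc": float(np.trapezoid(mean_tpr, grid)),
            }
    return out


def kfold_cv(
    dataset: Sequence[FeatureRow],
    k: int = 10,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with pooled out-of-fold scoring."""
    rows = list(dataset)
    config = config or TrainConfig()
    if k < 2:
        raise ContractError(f"k must be >= 2, got {k}")
    if k > len(rows):
        raise ContractError(f"k={k} exceeds the {len(rows)} available samples")
    folds = _fold_assignment(rows, k, seed)
    y_pred, scores, fold_acc = _out_of_fold(rows, folds, k, config)
    y_true = [r.class_label for r in rows]
    report = evaluate_predictions(y_true, y_pred, scores, protocol="kfold_cv")
    report.predictions = y_pred
    report.per_fold_accuracy = fold_acc
    report.mean_roc = _vertical_mean_roc(rows, folds, k, scores)
    return report


def jackknife(
    dataset: Sequence[FeatureRow], config: TrainConfig | None = None
) -> EvaluationReport:
    """Leave-one-out validation: n rounds, pooled predictions, no randomness."""
    rows = list(dataset)
    config = config or TrainConfig()
    if len(rows) < 3:
        raise ContractError(f"jackknife needs at least 3 samples, got {len(rows)}")
    folds = np.arange(len(rows), dtype=np.int64)  # one singleton fold per sample
    y_pred, scores, _ = _out_of_fold(rows, folds, len(rows), config)
    y_true = [r.class_label for r in rows]
    report = evaluate_predictions(y_true, y_pred, scores, protocol="jackknife")
    report.predictions = y_pred
    return report


def independent_test(
    dataset: Sequence[FeatureRow],
    train_fraction: float = 0.7,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Stratified split, train on one side, report on the disjoint other."""
    split = stratified_split(list(dataset), train_fraction=train_fraction, seed=seed)
    model = train(list(split.train), config)
    test = list(split.test)
    y_true = [r.class_label for r in test]
    y_pred = predict(model, test)
    report = evaluate_predictions(
        y_true, y_pred, predict_proba(model, test), protocol="independent_test"
    )
    report.predictions = y_pred
    return report
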