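"""Confusion-matrix metrics and stratified k-fold cross-validation.

Seven quantities are reported, all as percentages: sensitivity (TPR),
specificity (TNR), precision (PPV), F-score (harmonic mean of PPV and TPR),
Dice similarity coefficient (2TP / (2TP+FP+FN)), a balanced-accuracy AUC
((TPR+TNR)/2) and accuracy.  The balanced-accuracy form of AUC is the
default because it is what hard-label confusion counts support; a
rank-based ROC AUC is available where scores exist.

Reported values are rounded half-up to two decimals; fold averages are the
(re-rounded) means of the rounded per-fold values, matching how summary
tables are conventionally derived from per-fold tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classification import ClassifierSpec, train_classifier

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "FoldPlan",
    "round_half_up",
    "confusion",
    "confusion_from_masks",
    "metrics",
    "average_metrics",
    "cross_validate",
    "METRIC_NAMES",
]

METRIC_NAMES = ("DSC", "PPV", "TPR", "TNR", "F", "AUC", "accuracy")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (5 rounds up)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts (positives = pathological / tumor)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total < 1:
            raise ValueError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The seven evaluation percentages; ``None`` marks an undefined ratio.

    ``DSC``, ``PPV``, … are rounded half-up to two decimals; the raw,
    unrounded values are kept in ``raw``.
    """

    DSC: float | None
    PPV: float | None
    TPR: float | None
    TNR: float | None
    F: float | None
    AUC: float | None
    accuracy: float | None
    raw: dict | None = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold assignment: ``n_folds`` folds shuffled by ``seed``."""

    n_folds: int = 5
    seed: int = 0
    stratified: bool = True

    def split(self, y: np.ndarray):
        y = np.asarray(y)
        splitter = StratifiedKFold(
            n_splits=self.n_folds, shuffle=True, random_state=self.seed
        )
        strata = y if self.stratified else np.zeros_like(y)
        yield from splitter.split(np.zeros((y.size, 1)), strata)


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Confusion counts of paired +1/-1 (or 1/0) label vectors."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    p = pred > 0
    t = truth > 0
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def confusion_from_masks(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Pixel-wise confusion between a predicted and a reference mask."""
    pred_mask = np.asarray(pred_mask)
    truth_mask = np.asarray(truth_mask)
    if pred_mask.shape != truth_mask.shape:
        raise ValueError("mask shapes differ")
    return confusion(pred_mask.ravel(), truth_mask.ravel())


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """The seven metrics of a confusion matrix; zero-denominator ratios are
    reported as ``None`` (missing), never as 0."""
    tpr = _ratio(c.tp, c.tp + c.fn)
    tnr = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    dsc = _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    f = (
        None
        if ppv is None or tpr is None or (ppv + tpr) == 0
        else 2 * ppv * tpr / (ppv + tpr)
    )
    auc = None if tpr is None or tnr is None else (tpr + tnr) / 2.0
    acc = _ratio(c.tp + c.tn, c.total)
    raw = {"DSC": dsc, "PPV": ppv, "TPR": tpr, "TNR": tnr, "F": f, "AUC": auc,
           "accuracy": acc}
    rounded = {
        k: (None if v is None else round_half_up(v)) for k, v in raw.items()
    }
    return MetricSet(**rounded, raw=raw)


def f_score(ppv: float, tpr: float) -> float:
    """Harmonic mean of precision and sensitivity (both in percent)."""
    return 2.0 * ppv * tpr / (ppv + tpr)


def balanced_auc(tpr: float, tnr: float) -> float:
    """(TPR + TNR) / 2 — AUC of the single-operating-point ROC polygon."""
    return (tpr + tnr) / 2.0


def average_metrics(per_fold: list[MetricSet]) -> MetricSet:
    """Mean of rounded per-fold metrics, re-rounded to two decimals.

    A metric missing in any fold is missing in the average.
    """
    values = {}
    for name in METRIC_NAMES:
        vals = [getattr(m, name) for m in per_fold]
        values[name] = (
            None if any(v is None for v in vals) else round_half_up(float(np.mean(vals)))
        )
    return MetricSet(**values, raw=None)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    plan: FoldPlan = FoldPlan(),
) -> tuple[list[MetricSet], MetricSet]:
    """Stratified k-fold cross-validation of one classifier.

    Each fold is held out once; the classifier is trained on the remaining
    folds and scored on the held-out fold.  Returns the per-fold metric sets
    and their average.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    per_fold: list[MetricSet] = []
    for train_idx, test_idx in plan.split(y):
        if len(np.unique(y[train_idx])) < 2:
            raise ValueError("a training split lost one class; use stratified folds")
        model = train_classifier(spec, X[train_idx], y[train_idx], seed=plan.seed)
        pred = model.predict(X[test_idx])
        per_fold.append(metrics(confusion(pred, y[test_idx])))
    return per_fold, average_metrics(per_fold)
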