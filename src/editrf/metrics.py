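"""Confusion-matrix metrics and seeded stratified cross-validation.

The four performance measures are the standard binary-classification
set, with the positive class = RNA-editing site:

    Sn  = TP / (TP + FN)                      (sensitivity, recall)
    Sp  = TN / (TN + FP)                      (specificity)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC is the primary evaluator: it stays informative on imbalanced data
where accuracy saturates.  When any factor of the MCC denominator is
zero, MCC is defined as 0 (the usual convention for a degenerate
confusion matrix).  Sn (or Sp) is NaN when no positives (negatives)
were evaluated, and such NaNs are ignored when fold metrics are
averaged.

Cross-validation is 10-fold by default, stratified (folds drawn by
seeded shuffling within each class) and *pooled*: every fold's test
predictions are collected into one confusion matrix over all samples,
and the metrics are computed once.  Mean-of-fold metrics are available
via ``pooled=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .datasets import DatasetError, LabeledDataset
from .forest import RFConfig, VotingRandomForest

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVConfig",
    "confusion",
    "compute_metrics",
    "make_folds",
    "cross_validate",
    "repeated_cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sn/Sp/Acc in [0,1] (NaN when undefined), MCC in [-1,1]."""

    sn: float
    sp: float
    acc: float
    mcc: float

    def round(self, digits: int = 3) -> "MetricSet":
        return MetricSet(*(round(v, digits) for v in (self.sn, self.sp, self.acc, self.mcc)))


@dataclass
class CVConfig:
    folds: int = 10
    seed: int = 0
    stratified: bool = True
    pooled: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def _check_binary(v: np.ndarray, what: str) -> np.ndarray:
    v = np.asarray(v)
    uniq = set(np.unique(v).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"{what} must contain only 0/1, got {sorted(uniq)}")
    return v.astype(int)


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN with positive = 1."""
    y = _check_binary(labels, "labels")
    p = _check_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Evaluate Sn, Sp, Acc and MCC from confusion counts.

    Exact integer arithmetic is used for the MCC numerator and the
    denominator product, so large counts cannot overflow.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated samples")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else math.nan
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else math.nan
    acc = (c.tp + c.tn) / c.total
    den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if den == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(den)
    return MetricSet(sn=sn, sp=sp, acc=acc, mcc=mcc)


def make_folds(
    labels: np.ndarray, cv: CVConfig
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded (train_idx, test_idx) pairs; stratified within class by default."""
    y = _check_binary(labels, "labels")
    n = y.size
    if cv.folds > n:
        raise DatasetError(f"{cv.folds} folds but only {n} samples")
    if cv.stratified:
        smallest = min(int(np.sum(y == 0)), int(np.sum(y == 1)))
        if smallest < cv.folds:
            raise DatasetError(
                f"stratified {cv.folds}-fold CV needs >= {cv.folds} samples per "
                f"class (smallest class has {smallest})"
            )
        splitter = StratifiedKFold(cv.folds, shuffle=True, random_state=cv.seed)
    else:
        splitter = KFold(cv.folds, shuffle=True, random_state=cv.seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros((n, 1)), y)]


def _cv_predictions(
    dataset: LabeledDataset,
    feature_subset: list[str],
    rf: RFConfig,
    folds: list[tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Out-of-fold predictions for every sample (one forest per fold)."""
    X = dataset.table.subset(list(feature_subset)).values
    y = dataset.labels
    preds = np.full(y.size, -1, dtype=int)
    for tr, te in folds:
        est = VotingRandomForest(
            n_trees=rf.n_trees,
            features_per_split=rf.features_per_split,
            max_depth=rf.max_depth,
            random_state=rf.seed,
        ).fit(X[tr], y[tr])
        preds[te] = est.predict(X[te])
    assert np.all(preds >= 0), "every sample must land in exactly one test fold"
    return preds


def cross_validate(
    dataset: LabeledDataset,
    feature_subset: list[str],
    rf: RFConfig | None = None,
    cv: CVConfig | None = None,
) -> MetricSet:
    """k-fold CV of the forest on a feature subset; pooled by default."""
    rf = rf or RFConfig()
    cv = cv or CVConfig()
    dataset.require_both_classes()
    folds = make_folds(dataset.labels, cv)
    preds = _cv_predictions(dataset, feature_subset, rf, folds)
    if cv.pooled:
        return compute_metrics(confusion(dataset.labels, preds))
    per_fold = [
        compute_metrics(confusion(dataset.labels[te], preds[te])) for _, te in folds
    ]
    agg = [
        float(np.nanmean([getattr(m, f) for m in per_fold]))
        for f in ("sn", "sp", "acc", "mcc")
    ]
    return MetricSet(*agg)


def repeated_cross_validate(
    dataset: LabeledDataset,
    feature_subset: list[str],
    rf: RFConfig | None = None,
    cv: CVConfig | None = None,
    repeats: int = 10,
) -> list[MetricSet]:
    """Repeat CV with shifted fold seeds, for variance estimation."""
    cv = cv or CVConfig()
    out = []
    for r in range(repeats):
        cfg = CVConfig(cv.folds, cv.seed + r, cv.stratified, cv.pooled)
        out.append(cross_validate(dataset, feature_subset, rf, cfg))
    return out
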