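"""Incremental feature selection (IFS) over an mRMR ranking.

Features are added one at a time in rank order; for each nested set of
the top-k features a forest is evaluated by cross-validation, tracing an
IFS curve of k versus Sn/Sp/Acc/MCC.  The optimal feature count is the
smallest k attaining the maximum MCC (parsimony tie-break), and the
final model is trained once on the full dataset restricted to those
top-k features.

The same fold assignment is reused for every k by default, so points on
the curve are paired comparisons (less seed noise between adjacent k);
``shared_folds=False`` redraws folds per k instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .datasets import FeatureTable, LabeledDataset
from .forest import RFConfig, TrainedModel, train
from .metrics import CVConfig, MetricSet, compute_metrics, confusion, _cv_predictions, make_folds
from .mrmr import RankedFeatures, rank_features

__all__ = ["IFSRecord", "IFSCurve", "ifs_curve", "select_final_model", "IFSClassifier"]


@dataclass(frozen=True)
class IFSRecord:
    k: int
    metrics: MetricSet


@dataclass
class IFSCurve:
    """Per-k CV metrics for k = 1..N plus the selected optimum."""

    records: list[IFSRecord]
    optimal_k: int
    optimal_metrics: MetricSet

    def __len__(self) -> int:
        return len(self.records)

    def mcc_values(self) -> np.ndarray:
        return np.array([r.metrics.mcc for r in self.records])

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": [r.k for r in self.records],
                "Sn": [r.metrics.sn for r in self.records],
                "Sp": [r.metrics.sp for r in self.records],
                "Acc": [r.metrics.acc for r in self.records],
                "MCC": [r.metrics.mcc for r in self.records],
            }
        )


def _optimum(records: list[IFSRecord]) -> tuple[int, MetricSet]:
    mcc = np.array([r.metrics.mcc for r in records])
    i = int(np.argmax(mcc))  # first max ⇒ smallest k on ties
    return records[i].k, records[i].metrics


def ifs_curve(
    dataset: LabeledDataset,
    ranking: RankedFeatures,
    rf: RFConfig | None = None,
    cv: CVConfig | None = None,
    shared_folds: bool = True,
) -> IFSCurve:
    """Evaluate every nested top-k feature set of the ranking by CV."""
    rf = rf or RFConfig()
    cv = cv or CVConfig()
    missing = set(ranking.feature_names) - set(dataset.table.feature_names)
    if missing:
        raise ValueError(f"ranking names absent from dataset: {sorted(missing)}")
    if len(ranking) != dataset.n_features:
        raise ValueError(
            f"ranking covers {len(ranking)} of {dataset.n_features} features"
        )
    folds = make_folds(dataset.labels, cv)
    records: list[IFSRecord] = []
    for k in range(1, len(ranking) + 1):
        if not shared_folds and k > 1:
            folds = make_folds(
                dataset.labels, CVConfig(cv.folds, cv.seed + k, cv.stratified, cv.pooled)
            )
        preds = _cv_predictions(dataset, ranking.top(k), rf, folds)
        if cv.pooled:
            m = compute_metrics(confusion(dataset.labels, preds))
        else:
            per_fold = [
                compute_metrics(confusion(dataset.labels[te], preds[te]))
                for _, te in folds
            ]
            m = MetricSet(
                *(
                    float(np.nanmean([getattr(x, f) for x in per_fold]))
                    for f in ("sn", "sp", "acc", "mcc")
                )
            )
        records.append(IFSRecord(k, m))
    opt_k, opt_m = _optimum(records)
    return IFSCurve(records, opt_k, opt_m)


def select_final_model(
    dataset: LabeledDataset,
    curve: IFSCurve,
    ranking: RankedFeatures,
    rf: RFConfig | None = None,
) -> TrainedModel:
    """Train once on the full dataset restricted to the optimal top-k set."""
    return train(dataset, ranking.top(curve.optimal_k), rf or RFConfig())


class IFSClassifier(ClassifierMixin, BaseEstimator):
    """End-to-end mRMR + IFS + voting-forest classifier (sklearn API).

    ``fit`` ranks the features, traces the IFS curve under CV, picks the
    optimal k, and trains the final forest on the full training data;
    ``predict`` applies that forest to the same top-k columns.

    Attributes (after fit): ``ranking_`` (:class:`RankedFeatures`),
    ``curve_`` (:class:`IFSCurve`), ``optimal_k_``,
    ``selected_features_``, ``selected_indices_``, ``model_``.
    """

    def __init__(
        self,
        scheme: str = "MID",
        threshold_multiplier: float = 1.0,
        passthrough_levels: int = 3,
        n_trees: int = 10,
        max_depth: int | None = None,
        folds: int = 10,
        stratified: bool = True,
        pooled: bool = True,
        random_state: int = 0,
    ):
        self.scheme = scheme
        self.threshold_multiplier = threshold_multiplier
        self.passthrough_levels = passthrough_levels
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.folds = folds
        self.stratified = stratified
        self.pooled = pooled
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        names = (
            list(self.feature_names_in_)
            if hasattr(self, "feature_names_in_")
            else [f"x{j}" for j in range(X.shape[1])]
        )
        ds = LabeledDataset(FeatureTable(X, names), y)
        rf = RFConfig(
            n_trees=self.n_trees, max_depth=self.max_depth, seed=self.random_state
        )
        cv = CVConfig(
            folds=self.folds,
            seed=self.random_state,
            stratified=self.stratified,
            pooled=self.pooled,
        )
        self.ranking_ = rank_features(
            ds,
            scheme=self.scheme,
            threshold_multiplier=self.threshold_multiplier,
            passthrough_levels=self.passthrough_levels,
        )
        self.curve_ = ifs_curve(ds, self.ranking_, rf, cv)
        self.optimal_k_ = self.curve_.optimal_k
        self.selected_features_ = self.ranking_.top(self.optimal_k_)
        index = {f: j for j, f in enumerate(names)}
        self.selected_indices_ = np.array(
            [index[f] for f in self.selected_features_]
        )
        self.model_ = select_final_model(ds, self.curve_, self.ranking_, rf)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = validate_data(self, X, reset=False)
        return self.model_.estimator.predict(X[:, self.selected_indices_])
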