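"""Random-forest classification stage with a strict majority-vote contract.

The forest mirrors the defaults of the Weka 3.6.4 RandomForest that the
prediction protocol was designed around: 10 unpruned trees, bootstrap
row sampling, and ``floor(log2(M)) + 1`` candidate features per split
where M is the size of the active feature set.  The final label is the
class with the most tree votes; an exact tie (possible with an even
tree count) resolves to the negative class so predictions are
deterministic.  Modern practice favors more trees (e.g. 100) for lower
cross-validation variance; ``n_trees`` is a plain parameter.

The tree ensemble itself is scikit-learn's ``RandomForestClassifier``;
vote counting is done here because sklearn's own ``predict`` averages
class probabilities rather than counting hard votes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted, validate_data

from .datasets import DatasetError, FeatureTable, LabeledDataset

__all__ = [
    "RFConfig",
    "VotingRandomForest",
    "TrainedModel",
    "train",
    "predict",
    "save_model",
    "load_model",
    "weka_features_per_split",
]


def weka_features_per_split(n_features: int) -> int:
    """Weka's default mtry: floor(log2(M)) + 1, clipped to [1, M]."""
    if n_features < 1:
        raise ValueError("need at least one feature")
    return max(1, min(n_features, int(np.floor(np.log2(n_features))) + 1))


@dataclass
class RFConfig:
    """Forest hyperparameters (Weka 3.6.4 RandomForest defaults)."""

    n_trees: int = 10
    features_per_split: int | str = "log2plus1"
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def resolve_mtry(self, n_features: int) -> int:
        if self.features_per_split == "log2plus1":
            return weka_features_per_split(n_features)
        m = int(self.features_per_split)
        if not 1 <= m <= n_features:
            raise ValueError(f"features_per_split must be in [1, {n_features}]")
        return m


def majority_vote(tree_votes: np.ndarray, tie_class: int = 0) -> np.ndarray:
    """Reduce an (n_trees, n_samples) 0/1 vote matrix to labels.

    Strict majority elects class 1; ties go to ``tie_class``.
    """
    votes = np.asarray(tree_votes)
    n_trees = votes.shape[0]
    pos = votes.sum(axis=0)
    out = (2 * pos > n_trees).astype(int)
    if tie_class == 1:
        out[2 * pos == n_trees] = 1
    return out


class VotingRandomForest(ClassifierMixin, BaseEstimator):
    """Binary random forest predicting by hard majority vote over trees."""

    def __init__(
        self,
        n_trees: int = 10,
        features_per_split: int | str = "log2plus1",
        max_depth: int | None = None,
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.features_per_split = features_per_split
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        uniq = set(np.unique(y).tolist())
        if not uniq <= {0, 1}:
            raise DatasetError(f"labels must be 0/1, got {sorted(uniq)}")
        if len(uniq) < 2:
            raise DatasetError("training requires both classes")
        cfg = RFConfig(
            n_trees=self.n_trees,
            features_per_split=self.features_per_split,
            max_depth=self.max_depth,
            seed=self.random_state,
        )
        self.forest_ = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            max_features=cfg.resolve_mtry(X.shape[1]),
            max_depth=cfg.max_depth,
            bootstrap=True,
            random_state=cfg.seed,
        ).fit(X, y.astype(int))
        self.classes_ = np.array([0, 1])
        return self

    def _tree_votes(self, X) -> np.ndarray:
        # each sub-tree predicts indices into forest_.classes_
        cls = self.forest_.classes_
        return np.stack(
            [cls[t.predict(X).astype(int)] for t in self.forest_.estimators_]
        )

    def predict(self, X):
        check_is_fitted(self, "forest_")
        X = validate_data(self, X, reset=False)
        return majority_vote(self._tree_votes(X), tie_class=0)


@dataclass
class TrainedModel:
    """A fitted forest bound to the ordered feature names it was trained on."""

    estimator: VotingRandomForest
    feature_names: list[str]
    config: RFConfig = field(default_factory=RFConfig)


def train(
    dataset: LabeledDataset,
    feature_subset: list[str],
    config: RFConfig | None = None,
) -> TrainedModel:
    """Fit a forest on the dataset restricted to ``feature_subset``.

    Deterministic given (data, subset, seed).  Unknown feature names and
    single-class labels are errors.
    """
    config = config or RFConfig()
    dataset.require_both_classes()
    sub = dataset.table.subset(list(feature_subset))
    est = VotingRandomForest(
        n_trees=config.n_trees,
        features_per_split=config.features_per_split,
        max_depth=config.max_depth,
        random_state=config.seed,
    ).fit(sub.values, dataset.labels)
    return TrainedModel(est, list(feature_subset), config)


def predict(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Majority-vote predictions, aligning columns by name."""
    sub = table.subset(model.feature_names)
    return model.estimator.predict(sub.values)


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(model, path)


def load_model(path: str | Path) -> TrainedModel:
    model = joblib.load(path)
    if not isinstance(model, TrainedModel):
        raise TypeError(f"{path} does not contain a TrainedModel")
    return model
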