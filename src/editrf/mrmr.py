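"""Greedy maximum-relevance / minimum-redundancy (mRMR) feature ranking.

Relevance of a feature is its mutual information (MI) with the class
label; redundancy is its mean MI with the features already selected.
The greedy ranking picks, at each step, the unselected feature with the
best trade-off:

* **MID** (difference form, default): ``score = relevance − mean_redundancy``
* **MIQ** (quotient form): ``score = relevance / max(mean_redundancy, ε)``

Step 1 has an empty selected set: the redundancy term is 0 (MID) and the
score equals the relevance (MIQ), so the first pick is always the
maximum-relevance feature under either scheme.  Ties break toward the
lowest original column index.  All features are ranked, producing a full
ordering from best to worst trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .datasets import DatasetError, FeatureTable, LabeledDataset
from .discretize import discretize_table, mutual_information

__all__ = ["RankedFeatures", "MRMRSelector", "rank_features"]

SCHEMES = ("MID", "MIQ")


@dataclass
class RankedFeatures:
    """A complete mRMR ordering with per-step diagnostics.

    All per-feature arrays are aligned with ``feature_names`` (rank
    order, best first), not with the original column order.
    ``order`` holds the original 0-based column indices and is ``None``
    for rankings re-read from disk, where only names survive.
    """

    feature_names: list[str]
    relevance: np.ndarray
    step_score: np.ndarray
    redundancy: np.ndarray
    scheme: str = "MID"
    order: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        n = len(self.feature_names)
        if n == 0:
            raise ValueError("empty ranking")
        for arr in (self.relevance, self.step_score, self.redundancy):
            if len(arr) != n:
                raise ValueError("per-feature arrays must match feature_names")

    def __len__(self) -> int:
        return len(self.feature_names)

    def top(self, k: int) -> list[str]:
        if not 1 <= k <= len(self):
            raise ValueError(f"k must be in [1, {len(self)}]")
        return self.feature_names[:k]


def _greedy_rank(
    states: np.ndarray, y: np.ndarray, scheme: str, eps: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run the greedy forward scan on a discretized matrix.

    Returns (order, relevance, step_score, redundancy), all in rank order.
    Pairwise feature MI is computed lazily: selecting feature *s* adds
    MI(f, s) to every remaining candidate's running redundancy sum.
    """
    n_feat = states.shape[1]
    relevance = np.array(
        [mutual_information(states[:, j], y) for j in range(n_feat)]
    )
    remaining = np.ones(n_feat, dtype=bool)
    red_sum = np.zeros(n_feat)
    order = np.empty(n_feat, dtype=np.int64)
    sel_score = np.empty(n_feat)
    sel_red = np.empty(n_feat)
    for step in range(n_feat):
        if step == 0:
            red_mean = np.zeros(n_feat)
            scores = relevance.copy()
        else:
            red_mean = red_sum / step
            if scheme == "MID":
                scores = relevance - red_mean
            else:
                scores = relevance / np.maximum(red_mean, eps)
        masked = np.where(remaining, scores, -np.inf)
        j = int(np.argmax(masked))  # first max ⇒ lowest-index tie-break
        order[step] = j
        sel_score[step] = scores[j]
        sel_red[step] = red_mean[j]
        remaining[j] = False
        if step < n_feat - 1:
            sel_col = states[:, j]
            for f in np.flatnonzero(remaining):
                red_sum[f] += mutual_information(states[:, f], sel_col)
    return order, relevance[order], sel_score, sel_red


class MRMRSelector(SelectorMixin, BaseEstimator):
    """mRMR feature ranking as a scikit-learn feature selector.

    ``fit`` computes the full greedy ordering; ``transform`` keeps the
    top-``k`` ranked features (all of them when ``k`` is None, i.e. a
    pure reordering diagnostic).  Composes with sklearn pipelines.

    Parameters
    ----------
    k : int or None
        Number of top-ranked features ``transform`` retains.
    scheme : {"MID", "MIQ"}
        Difference or quotient trade-off form.
    threshold_multiplier : float
        ``t`` in the mean ± t·sd three-state discretization.
    passthrough_levels : int
        Columns with at most this many distinct values skip
        discretization (0 disables the bypass).
    eps : float
        Floor for the MIQ mean-redundancy divisor.

    Attributes
    ----------
    ranking_ : ndarray of original column indices, best first.
    relevance_, step_scores_, redundancy_ : per-step diagnostics in
        rank order.
    """

    def __init__(
        self,
        k: int | None = None,
        scheme: str = "MID",
        threshold_multiplier: float = 1.0,
        passthrough_levels: int = 3,
        eps: float = 1e-12,
    ):
        self.k = k
        self.scheme = scheme
        self.threshold_multiplier = threshold_multiplier
        self.passthrough_levels = passthrough_levels
        self.eps = eps

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_features=1)
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        classes = np.unique(y)
        if classes.size < 2:
            raise DatasetError("mRMR ranking needs both classes in the labels")
        if self.k is not None and not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k must be in [1, {X.shape[1]}]")
        names = [f"x{j}" for j in range(X.shape[1])]
        table = FeatureTable(X, names)
        disc = discretize_table(
            table, self.threshold_multiplier, self.passthrough_levels
        )
        _, y_codes = np.unique(y, return_inverse=True)
        order, rel, score, red = _greedy_rank(
            disc.states, y_codes, self.scheme, self.eps
        )
        self.ranking_ = order
        self.relevance_ = rel
        self.step_scores_ = score
        self.redundancy_ = red
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "ranking_")
        k = len(self.ranking_) if self.k is None else self.k
        mask = np.zeros(len(self.ranking_), dtype=bool)
        mask[self.ranking_[:k]] = True
        return mask


def rank_features(
    dataset: LabeledDataset,
    scheme: str = "MID",
    threshold_multiplier: float = 1.0,
    passthrough_levels: int = 3,
    eps: float = 1e-12,
) -> RankedFeatures:
    """Rank all features of a labeled dataset by the mRMR criterion."""
    dataset.require_both_classes()
    sel = MRMRSelector(
        scheme=scheme,
        threshold_multiplier=threshold_multiplier,
        passthrough_levels=passthrough_levels,
        eps=eps,
    ).fit(dataset.table.values, dataset.labels)
    names = [dataset.table.feature_names[j] for j in sel.ranking_]
    return RankedFeatures(
        feature_names=names,
        relevance=sel.relevance_,
        step_score=sel.step_scores_,
        redundancy=sel.redundancy_,
        scheme=scheme,
        order=sel.ranking_,
    )
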