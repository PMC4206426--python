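"""In-memory containers for labeled feature tables.

A :class:`FeatureTable` is a dense real matrix of per-site alignment
features (samples × features) with ordered, unique feature names and
optional sample identifiers.  A :class:`LabeledDataset` pairs a table
with a binary label vector (1 = RNA-editing / positive class,
0 = non-editing / negative class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DatasetError", "FeatureTable", "LabeledDataset"]


class DatasetError(ValueError):
    """Raised when a feature table or label vector violates its contract."""


def _check_unique(names: list[str], what: str) -> None:
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise DatasetError(f"duplicate {what}: {n!r}")
        seen.add(n)


@dataclass
class FeatureTable:
    """Samples × features matrix of real-valued, unitless feature values.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_samples, n_features)``.  All entries
        must be finite; missing data is an error at construction time.
    feature_names
        Ordered, unique column names, one per feature.
    sample_ids
        Ordered, unique row identifiers; auto-generated (``s0001`` ...)
        when omitted.
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DatasetError("feature values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise DatasetError("need at least one sample and one feature")
        if not np.all(np.isfinite(self.values)):
            raise DatasetError("feature matrix contains missing or non-finite entries")
        self.feature_names = [str(f) for f in self.feature_names]
        if len(self.feature_names) != p:
            raise DatasetError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        _check_unique(self.feature_names, "feature name")
        if self.sample_ids is None:
            self.sample_ids = [f"s{i + 1:04d}" for i in range(n)]
        else:
            self.sample_ids = [str(s) for s in self.sample_ids]
            if len(self.sample_ids) != n:
                raise DatasetError(f"{len(self.sample_ids)} sample ids for {n} rows")
            _check_unique(self.sample_ids, "sample id")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.feature_names.index(name)
        except ValueError:
            raise DatasetError(f"unknown feature: {name!r}") from None
        return self.values[:, j]

    def subset(self, names: list[str]) -> "FeatureTable":
        """Return a table restricted to ``names``, in the given order.

        Missing columns are an error; this is how a trained model aligns a
        prediction table to its training feature set.
        """
        if not names:
            raise DatasetError("empty feature subset")
        index = {f: j for j, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise DatasetError(f"missing feature columns: {missing}")
        cols = [index[f] for f in names]
        return FeatureTable(self.values[:, cols], list(names), list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=self.feature_names, index=pd.Index(self.sample_ids)
        )


@dataclass
class LabeledDataset:
    """A feature table plus a binary label per sample (1 = editing site)."""

    table: FeatureTable
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or len(self.labels) != self.table.n_samples:
            raise DatasetError("labels must be a vector with one entry per sample")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {0, 1}:
            raise DatasetError(f"labels must be binary 0/1, got values {sorted(uniq)}")
        self.labels = self.labels.astype(int)

    @property
    def n_samples(self) -> int:
        return self.table.n_samples

    @property
    def n_features(self) -> int:
        return self.table.n_features

    @property
    def class_counts(self) -> tuple[int, int]:
        """(negatives, positives)."""
        pos = int(self.labels.sum())
        return self.table.n_samples - pos, pos

    def require_both_classes(self) -> None:
        neg, pos = self.class_counts
        if neg == 0 or pos == 0:
            raise DatasetError(
                f"training requires both classes; got {pos} positives, {neg} negatives"
            )
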