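"""Three-state discretization and plug-in information measures.

Mutual-information feature ranking needs discrete variables.  Continuous
features are mapped to states {-1, 0, +1} by thresholding at
``mean ± t·sd`` (population standard deviation, ``t`` = 1 by default),
the convention of the classic mRMR program.  Columns that are already
discrete — at most ``passthrough_levels`` distinct values, such as a 0/1
repeat-region indicator — bypass thresholding and keep their own small
alphabet.

Entropy and mutual information are plug-in (empirical-frequency)
estimates in bits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import FeatureTable

__all__ = [
    "DiscretizedTable",
    "discretize_feature",
    "discretize_table",
    "entropy",
    "mutual_information",
]


def discretize_feature(
    values: np.ndarray, threshold_multiplier: float = 1.0
) -> np.ndarray:
    """Map a continuous vector to states {-1, 0, +1} at mean ± t·sd.

    ``sd`` is the population (1/n) standard deviation.  A constant vector
    (sd = 0) maps to all zeros.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("values must be a non-empty 1-D vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    t = float(threshold_multiplier)
    if not t > 0:
        raise ValueError("threshold_multiplier must be positive")
    states = np.zeros(v.size, dtype=np.int64)
    sd = v.std()  # population sd
    if sd == 0.0:
        return states
    m = v.mean()
    states[v > m + t * sd] = 1
    states[v < m - t * sd] = -1
    return states


@dataclass
class DiscretizedTable:
    """Integer-state view of a :class:`FeatureTable` (same shape)."""

    states: np.ndarray
    feature_names: list[str]


def discretize_table(
    table: FeatureTable,
    threshold_multiplier: float = 1.0,
    passthrough_levels: int = 3,
) -> DiscretizedTable:
    """Discretize every column of a feature table.

    Columns with at most ``passthrough_levels`` distinct values are
    treated as already discrete and re-encoded as consecutive integers
    (mutual information is invariant to state relabeling); all others go
    through :func:`discretize_feature`.
    """
    n, p = table.values.shape
    states = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        col = table.values[:, j]
        uniq, inverse = np.unique(col, return_inverse=True)
        if passthrough_levels and uniq.size <= passthrough_levels:
            states[:, j] = inverse
        else:
            states[:, j] = discretize_feature(col, threshold_multiplier)
    return DiscretizedTable(states, list(table.feature_names))


def _counts(x: np.ndarray) -> np.ndarray:
    _, c = np.unique(x, return_counts=True)
    return c


def entropy(states: np.ndarray) -> float:
    """Plug-in Shannon entropy in bits; 0·log 0 ≡ 0."""
    x = np.asarray(states)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("states must be a non-empty 1-D vector")
    p = _counts(x) / x.size
    return float(-(p * np.log2(p)).sum())


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information in bits, H(x) + H(y) − H(x, y).

    Symmetric, non-negative (clamped against roundoff), and equal to the
    entropy when ``x`` is ``y``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.ndim != 1 or y.ndim != 1 or x.size == 0:
        raise ValueError("inputs must be non-empty 1-D vectors")
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    _, xc = np.unique(x, return_inverse=True)
    uy, yc = np.unique(y, return_inverse=True)
    joint = xc * uy.size + yc
    mi = entropy(xc) + entropy(yc) - entropy(joint)
    return max(0.0, mi)
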