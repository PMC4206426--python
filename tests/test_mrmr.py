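"""Greedy mRMR ranking: step rule, tie-breaks, and selector API."""

import numpy as np
import pytest
from sklearn.base import clone

from editrf import (
    DatasetError,
    FeatureTable,
    LabeledDataset,
    MRMRSelector,
    rank_features,
)
from editrf.discretize import discretize_table, mutual_information


def brute_force_order(states, y, scheme="MID", eps=1e-12):
    """Independent re-implementation of the greedy step rule.

    At every step, score *every* unselected feature from scratch
    (no incremental redundancy bookkeeping) and pick the best,
    lowest index on ties.
    """
    p = states.shape[1]
    selected = []
    while len(selected) < p:
        best_j, best_score = None, None
        for j in range(p):
            if j in selected:
                continue
            rel = mutual_information(states[:, j], y)
            if not selected:
                score = rel
            else:
                red = np.mean(
                    [mutual_information(states[:, j], states[:, s]) for s in selected]
                )
                score = rel - red if scheme == "MID" else rel / max(red, eps)
            if best_score is None or score > best_score + 1e-15:
                best_j, best_score = j, score
        selected.append(best_j)
    return selected


def dataset_from(columns: dict, y) -> LabeledDataset:
    names = list(columns)
    X = np.column_stack([np.asarray(columns[n], float) for n in names])
    return LabeledDataset(FeatureTable(X, names), np.asarray(y))


Y12 = np.array([0] * 6 + [1] * 6)


class TestRanking:
    def test_max_relevance_feature_ranked_first(self):
        ds = dataset_from({"const": [3.0] * 12, "labelcopy": Y12}, Y12)
        r = rank_features(ds)
        assert r.feature_names[0] == "labelcopy"
        assert r.relevance[0] == pytest.approx(1.0)
        assert r.step_score[0] == pytest.approx(r.relevance[0])  # step 1 = relevance

    def test_duplicate_is_penalized_below_weak_independent_signal(self):
        # f1 strongly (not perfectly) informative, f2 its exact duplicate,
        # f3 a weak signal independent of f1: redundancy must demote f2.
        f1 = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 0])
        f3 = np.array([0, 1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 1])
        ds = dataset_from({"f1": f1, "f2": f1.copy(), "f3": f3}, Y12)
        r = rank_features(ds, scheme="MID")
        assert r.feature_names == ["f1", "f3", "f2"]
        # duplicate's step score is relevance - H(f1) < 0
        assert r.step_score[2] < 0

    def test_complete_permutation(self, small_synth):
        r = rank_features(small_synth)
        assert sorted(r.order.tolist()) == list(range(small_synth.n_features))
        assert sorted(r.feature_names) == sorted(small_synth.table.feature_names)

    def test_constant_noise_feature_never_displaces_first(self, small_synth):
        r0 = rank_features(small_synth)
        X = np.column_stack([small_synth.table.values, np.full(small_synth.n_samples, 7.0)])
        names = small_synth.table.feature_names + ["flat"]
        ds = LabeledDataset(FeatureTable(X, names), small_synth.labels)
        assert rank_features(ds).feature_names[0] == r0.feature_names[0]

    @pytest.mark.parametrize("scheme", ["MID", "MIQ"])
    def test_matches_exhaustive_step_scan(self, scheme, small_synth):
        # greedy incremental bookkeeping vs from-scratch scan, <= 6 features
        sub = small_synth.table.subset(small_synth.table.feature_names[:6])
        ds = LabeledDataset(sub, small_synth.labels)
        disc = discretize_table(sub)
        expected = brute_force_order(disc.states, ds.labels, scheme)
        got = rank_features(ds, scheme=scheme).order.tolist()
        assert got == expected

    def test_first_pick_invariant_between_schemes(self, small_synth):
        assert (
            rank_features(small_synth, scheme="MID").feature_names[0]
            == rank_features(small_synth, scheme="MIQ").feature_names[0]
        )

    def test_tie_break_prefers_lower_column_index(self):
        f = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 0, 0, 0])
        ds = dataset_from({"left": f, "right": f.copy()}, Y12)
        assert rank_features(ds).feature_names[0] == "left"

    def test_single_class_labels_rejected(self):
        ds = dataset_from({"a": np.arange(4.0)}, [1, 1, 1, 1])
        with pytest.raises(DatasetError):
            rank_features(ds)


class TestSelectorAPI:
    def test_transform_keeps_top_k_columns(self, small_synth):
        sel = MRMRSelector(k=3).fit(small_synth.table.values, small_synth.labels)
        Xt = sel.transform(small_synth.table.values)
        assert Xt.shape == (small_synth.n_samples, 3)
        assert sel.get_support().sum() == 3
        np.testing.assert_array_equal(
            np.sort(np.flatnonzero(sel.get_support())), np.sort(sel.ranking_[:3])
        )

    def test_clone_and_params_round_trip(self):
        sel = MRMRSelector(k=5, scheme="MIQ", threshold_multiplier=2.0)
        assert clone(sel).get_params() == sel.get_params()

    def test_invalid_k_rejected(self, small_synth):
        with pytest.raises(ValueError):
            MRMRSelector(k=99).fit(small_synth.table.values, small_synth.labels)
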