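"""Confusion counts, Sn/Sp/Acc/MCC formulas, and stratified pooled CV."""

import math
from fractions import Fraction

import numpy as np
import pytest

from editrf import (
    ConfusionCounts,
    CVConfig,
    DatasetError,
    FeatureTable,
    LabeledDataset,
    RFConfig,
    compute_metrics,
    confusion,
    cross_validate,
    make_folds,
    repeated_cross_validate,
)


def metrics_oracle(c: ConfusionCounts):
    """Exact-rational re-evaluation of the four formulas."""
    tp, tn, fp, fn = Fraction(c.tp), Fraction(c.tn), Fraction(c.fp), Fraction(c.fn)
    sn = float(tp / (tp + fn)) if tp + fn else math.nan
    sp = float(tn / (tn + fp)) if tn + fp else math.nan
    acc = float((tp + tn) / (tp + tn + fp + fn))
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)  # exact integer product
    mcc = 0.0 if den == 0 else float(tp * tn - fp * fn) / math.sqrt(float(den))
    return sn, sp, acc, mcc


class TestConfusion:
    @pytest.mark.parametrize(
        "labels,preds,expected",
        [
            ([1, 1, 0, 0], [1, 1, 0, 0], (2, 2, 0, 0)),
            ([1, 0], [0, 1], (0, 0, 1, 1)),
            ([1] * 5, [1] * 5, (5, 0, 0, 0)),
        ],
    )
    def test_counts(self, labels, preds, expected):
        c = confusion(np.array(labels), np.array(preds))
        assert (c.tp, c.tn, c.fp, c.fn) == expected
        assert c.total == len(labels)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.array([0, 1]), np.array([1]))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([0, 2]), np.array([0, 1]))


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_matches_exact_rational_oracle_on_random_counts(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            c = ConfusionCounts(*(int(v) for v in rng.integers(0, 500, 4)))
            if c.total == 0:
                continue
            m = compute_metrics(c)
            sn, sp, acc, mcc = metrics_oracle(c)
            for got, want in zip((m.sn, m.sp, m.acc, m.mcc), (sn, sp, acc, mcc)):
                if math.isnan(want):
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(want, abs=1e-12)

    def test_zero_denominator_mcc_is_zero(self):
        m = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m.mcc == 0.0
        assert math.isnan(m.sn)  # no positives evaluated
        assert m.sp == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_mcc_antisymmetric_under_prediction_inversion(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        m = compute_metrics(confusion(y, p))
        m_inv = compute_metrics(confusion(y, 1 - p))
        assert m_inv.mcc == pytest.approx(-m.mcc, abs=1e-12)


class TestFolds:
    def test_partition_property(self, small_synth):
        folds = make_folds(small_synth.labels, CVConfig(folds=5, seed=2))
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(small_synth.n_samples))
        for (_, a), (_, b) in zip(folds, folds[1:]):
            assert set(a).isdisjoint(b)

    def test_stratified_sizes_at_published_scale(self):
        # 127 + 127 samples in 10 folds -> sizes 25/26, classes within 1 of 1:1
        y = np.repeat([0, 1], 127)
        folds = make_folds(y, CVConfig(folds=10, seed=0))
        for _, te in folds:
            assert len(te) in (25, 26)
            pos = int(y[te].sum())
            assert abs(pos - (len(te) - pos)) <= 1

    def test_class_smaller_than_fold_count_rejected(self):
        y = np.array([1] * 3 + [0] * 40)
        with pytest.raises(DatasetError):
            make_folds(y, CVConfig(folds=10, seed=0))

    def test_seed_changes_assignment(self):
        y = np.repeat([0, 1], 30)
        f1 = make_folds(y, CVConfig(folds=5, seed=1))
        f2 = make_folds(y, CVConfig(folds=5, seed=2))
        assert any(set(a[1]) != set(b[1]) for a, b in zip(f1, f2))


class TestCrossValidate:
    def test_deterministic_given_seeds(self, small_synth):
        names = small_synth.table.feature_names[:4]
        m1 = cross_validate(small_synth, names, RFConfig(seed=9), CVConfig(folds=5, seed=9))
        m2 = cross_validate(small_synth, names, RFConfig(seed=9), CVConfig(folds=5, seed=9))
        assert m1 == m2

    def test_informative_subset_beats_chance(self, small_synth):
        m = cross_validate(
            small_synth, ["inf_1", "inf_2", "inf_3"], RFConfig(seed=0), CVConfig(folds=5, seed=0)
        )
        assert m.mcc > 0.5
        assert 0 <= m.acc <= 1

    def test_mean_of_folds_mode_runs(self, small_synth):
        m = cross_validate(
            small_synth,
            ["inf_1"],
            RFConfig(seed=0),
            CVConfig(folds=5, seed=0, pooled=False),
        )
        assert -1 <= m.mcc <= 1

    def test_unstratified_mode_runs(self, small_synth):
        m = cross_validate(
            small_synth,
            ["inf_1"],
            RFConfig(seed=0),
            CVConfig(folds=5, seed=0, stratified=False),
        )
        assert -1 <= m.mcc <= 1

    def test_repeats_vary_fold_seed(self, small_synth):
        out = repeated_cross_validate(
            small_synth, ["inf_1", "inf_2"], RFConfig(seed=0), CVConfig(folds=5, seed=0), repeats=3
        )
        assert len(out) == 3
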