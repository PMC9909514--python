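"""Splitting, aggregation, metrics, and the cross-validated runner."""

import numpy as np
import pandas as pd
import pytest

from readmood.cnn import CnnArchitecture, TrainConfig
from readmood.evaluate import (ExperimentConfig, aggregate_to_participant,
                               compute_metrics, make_splits,
                               partition_sizes, run_experiment)

from .oracles import mann_whitney_auc


def manifest_of(n_mdd, n_hc):
    ids = [f"M{i:03d}" for i in range(n_mdd)] + \
          [f"H{i:03d}" for i in range(n_hc)]
    groups = ["MDD"] * n_mdd + ["HC"] * n_hc
    return pd.DataFrame({"participant_id": ids, "group": groups})


class TestSplits:
    def test_study_sized_cohort_reproduces_254_32_32(self):
        plans = make_splits(manifest_of(153, 165), n_folds=10, seed=0)
        assert len(plans) == 10
        for p in plans:
            assert (len(p.train_ids), len(p.val_ids), len(p.test_ids)) \
                == (254, 32, 32)

    def test_ten_participants_split_8_1_1(self):
        assert partition_sizes(10) == (8, 1, 1)
        plans = make_splits(manifest_of(5, 5), n_folds=3, seed=1)
        for p in plans:
            assert (len(p.train_ids), len(p.val_ids), len(p.test_ids)) \
                == (8, 1, 1)

    def test_odd_remainder_extra_goes_to_validation(self):
        assert partition_sizes(11) == (8, 2, 1)

    def test_partitions_disjoint_and_exhaustive(self):
        m = manifest_of(20, 25)
        for p in make_splits(m, n_folds=5, seed=2):
            assert not (p.train_ids & p.test_ids)
            assert not (p.train_ids & p.val_ids)
            assert not (p.val_ids & p.test_ids)
            union = p.train_ids | p.val_ids | p.test_ids
            assert union == set(m.participant_id)

    def test_stratification_within_one_participant(self):
        m = manifest_of(153, 165)
        frac = 153 / 318
        groups = dict(zip(m.participant_id, m.group))
        for p in make_splits(m, n_folds=5, seed=3):
            for ids in (p.train_ids, p.val_ids, p.test_ids):
                n_mdd = sum(groups[i] == "MDD" for i in ids)
                assert abs(n_mdd - frac * len(ids)) <= 1.0

    def test_same_seed_reproducible_folds(self):
        m = manifest_of(10, 12)
        a = make_splits(m, n_folds=4, seed=5)
        b = make_splits(m, n_folds=4, seed=5)
        assert [(p.train_ids, p.test_ids) for p in a] == \
            [(p.train_ids, p.test_ids) for p in b]

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            make_splits(manifest_of(2, 10), n_folds=2)


class TestAggregate:
    def test_single_segment_passthrough(self):
        out = aggregate_to_participant(["A"], [0.7])
        assert out.loc[0, "prob"] == pytest.approx(0.7)
        assert out.loc[0, "pred"] == 1

    def test_mean_and_tie_rule(self):
        out = aggregate_to_participant(["A"] * 3, [0.2, 0.4, 0.9])
        assert out.loc[0, "prob"] == pytest.approx(0.5)
        assert out.loc[0, "pred"] == 1  # >= 0.5 maps to the positive class

    def test_permutation_invariant(self):
        ids = ["A", "B", "A", "B", "A"]
        probs = [0.1, 0.9, 0.3, 0.7, 0.5]
        a = aggregate_to_participant(ids, probs)
        order = [4, 2, 0, 3, 1]
        b = aggregate_to_participant([ids[i] for i in order],
                                     [probs[i] for i in order])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_to_participant([], [])


class TestMetrics:
    def test_hand_computed_confusion_matrix(self):
        # TP=30, FP=10, FN=10, TN=50
        y_true = [1] * 40 + [0] * 60
        y_pred = [1] * 30 + [0] * 10 + [1] * 10 + [0] * 50
        m = compute_metrics(y_true, y_pred)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.80)
        np.testing.assert_array_equal(m.confusion, [[50, 10], [10, 30]])

    def test_perfect_ranking_has_unit_auc(self):
        y = [0, 0, 1, 1]
        m = compute_metrics(y, y, [0.1, 0.2, 0.8, 0.9])
        assert m.auc == pytest.approx(1.0)
        assert m.accuracy == m.precision == m.recall == m.f1 == 1.0

    def test_trapezoid_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 2)  # duplicates exercise ties
            m = compute_metrics(y, (s >= 0.5).astype(int), s)
            assert m.auc == pytest.approx(mann_whitney_auc(y, s), abs=1e-9)

    def test_reversed_scores_complement_auc(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50)
        a = compute_metrics(y, (s >= 0.5).astype(int), s).auc
        b = compute_metrics(y, (s < 0.5).astype(int), -s).auc
        assert a + b == pytest.approx(1.0, abs=1e-9)

    def test_zero_division_flagged(self):
        m = compute_metrics([0, 0, 1], [0, 0, 0])
        assert m.precision == 0.0
        assert "zero_division" in m.flags

    def test_single_class_truth_omits_auc(self):
        m = compute_metrics([1, 1, 1], [1, 0, 1], [0.9, 0.2, 0.8])
        assert m.auc is None
        assert "auc_omitted_single_class" in m.flags

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])


@pytest.fixture(scope="module")
def report(small_cohort):
    _, recordings, _ = small_cohort
    cfg = ExperimentConfig(
        models=("cnn", "rf"), n_folds=3, seed=5,
        arch=CnnArchitecture(conv_channels=(4, 4, 4, 4),
                             dense_units=(8, 4)),
        train=TrainConfig(epochs=1, batch_size=32),
        max_train_segments=2, max_eval_segments=2)
    return run_experiment(recordings, cfg)


class TestRunExperiment:

    def test_bookkeeping_row_counts(self, report):
        assert not report.failures
        rows = report.rows
        # per fold: CNN at two levels + RF at participant level
        assert len(rows) == 3 * 3
        assert set(rows["model"]) == {"cnn", "rf"}
        assert set(rows[rows.model == "cnn"]["level"]) == \
            {"segment", "participant"}

    def test_all_metrics_within_unit_interval(self, report):
        metrics = report.rows[["accuracy", "precision", "recall", "f1"]]
        assert ((metrics >= 0) & (metrics <= 1)).all().all()
        aucs = report.rows["auc"].dropna()
        assert ((aucs >= 0) & (aucs <= 1)).all()

    def test_aggregates_consistent_with_fold_rows(self, report):
        agg = report.aggregates()
        rows = report.rows
        sel = (agg.task == "vowel") & (agg.model == "rf") \
            & (agg.level == "participant")
        manual = rows[(rows.model == "rf")]["accuracy"].mean()
        assert agg[sel]["accuracy_mean"].iloc[0] == pytest.approx(manual)

    def test_provenance_recorded(self, report):
        assert report.provenance["seed"] == 5
        assert report.provenance["n_folds"] == 3
        assert report.provenance["n_failures"] == 0
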