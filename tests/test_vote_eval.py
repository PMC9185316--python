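import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from auscult import (AudioRecording, ConfusionCounts, Label, PipelineConfig,
                     THRESHOLD_GRID, compute_metrics, generate_dataset,
                     kfold_evaluate, sweep_thresholds, vote_sample)
from auscult.vote_eval import _stratified_folds


class TestVoteSample:
    @pytest.mark.parametrize("labels,thr,expected", [
        ([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], 0.25, Label.ABNORMAL),  # 0.30 > 0.25
        ([0] * 10, 0.5, Label.NORMAL),
        ([1, 1, 0, 0, 0, 0, 0, 0, 0, 0], 0.20, Label.NORMAL),    # strict: 0.20 not > 0.20
    ])
    def test_rule_cases(self, labels, thr, expected):
        assert vote_sample(labels, thr).decision is expected

    def test_bookkeeping(self):
        d = vote_sample([1, 0, 1, 0], 0.4, parent_id="s1")
        assert (d.n_frames, d.n_abnormal_frames) == (4, 2)
        assert d.abnormal_fraction == 0.5
        assert d.parent_id == "s1"

    def test_brute_force_enumeration(self):
        # all frame-label vectors of length 1..8 against every grid threshold
        for n in range(1, 9):
            for labels in itertools.product([0, 1], repeat=n):
                frac = sum(labels) / n
                for thr in THRESHOLD_GRID:
                    expected = Label.ABNORMAL if frac > thr else Label.NORMAL
                    assert vote_sample(labels, thr).decision is expected

    @settings(derandomize=True, max_examples=200)
    @given(labels=st.lists(st.integers(0, 1), min_size=1, max_size=40),
           grid_idx=st.integers(1, 19))
    def test_decision_matches_fraction_rule(self, labels, grid_idx):
        thr = round(0.05 * grid_idx, 2)
        d = vote_sample(labels, thr)
        assert (d.decision is Label.ABNORMAL) == (sum(labels) / len(labels) > thr)
        assert d.n_abnormal_frames == sum(labels)

    def test_errors(self):
        with pytest.raises(ValueError):
            vote_sample([], 0.5)
        with pytest.raises(ValueError):
            vote_sample([1], 0.0)


class TestComputeMetrics:
    def test_hand_evaluated_counts(self):
        m = compute_metrics(ConfusionCounts(tp=8, fn=2, tn=9, fp=1))
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["precision"] == pytest.approx(0.8889, abs=1e-4)
        assert m["f1"] == pytest.approx(0.8421, abs=1e-4)

    def test_perfect_classification(self):
        m = compute_metrics(ConfusionCounts(tp=5, tn=7, fp=0, fn=0))
        assert all(m[k] == 1.0 for k in m)

    def test_degenerate_no_positives_predicted(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=4, tn=6))
        assert m["sensitivity"] == 0.0
        assert m["precision"] == 0.0
        assert m["f1"] == 0.0

    def test_accuracy_count_identity(self, rng):
        for _ in range(20):
            tp, tn, fp, fn = (int(x) for x in rng.integers(0, 20, 4))
            if tp + tn + fp + fn == 0:
                continue
            c = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
            m = compute_metrics(c)
            assert m["accuracy"] * c.total == pytest.approx(tp + tn)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestSweepThresholds:
    def test_nineteen_thresholds(self):
        table = sweep_thresholds([[1, 0], [0, 0]], [1, 0])
        assert len(table) == 19
        assert list(table.index) == [round(0.05 * k, 2) for k in range(1, 20)]

    def test_perfect_frames_give_accuracy_one_at_low_thresholds(self):
        frame_labels = [[1, 1, 1, 1], [0, 0, 0, 0], [1, 1, 1, 1]]
        table = sweep_thresholds(frame_labels, [1, 0, 1])
        # every true-abnormal fraction is 1.0, so all thresholds below 1 are perfect
        assert np.all(table["accuracy"] == 1.0)

    def test_sensitivity_specificity_monotone_in_threshold(self, rng):
        for _ in range(50):
            n_samples = int(rng.integers(2, 6))
            frame_labels = [rng.integers(0, 2, int(rng.integers(1, 7)))
                            for _ in range(n_samples)]
            truth = rng.integers(0, 2, n_samples)
            if truth.min() == truth.max():
                continue
            table = sweep_thresholds(frame_labels, truth)
            assert np.all(np.diff(table["sensitivity"]) <= 1e-12)
            assert np.all(np.diff(table["specificity"]) >= -1e-12)

    def test_misaligned_inputs(self):
        with pytest.raises(ValueError):
            sweep_thresholds([[1, 0]], [1, 0])


class TestKfold:
    def test_fold_partition_and_stratification(self):
        labels = np.r_[np.zeros(12, dtype=int), np.ones(8, dtype=int)]
        ids = np.arange(20)
        folds = _stratified_folds(ids, labels, k=5, seed=3)
        test_sets = [set(te) for _, te in folds]
        assert all(len(te) == 4 for te in test_sets)
        assert set().union(*test_sets) == set(range(20))
        assert sum(len(a & b) for a, b in itertools.combinations(test_sets, 2)) == 0
        for tr, te in folds:
            # per-fold class ratio within one sample of the global 60/40 split
            assert abs(labels[te].sum() - 8 / 5) <= 1
            assert np.unique(labels[tr]).size == 2

    def test_end_to_end_small_corpus(self):
        recs = generate_dataset(6, 6, "heart", seed=5, duration_s=6)
        cfg = PipelineConfig.for_kind("heart", frame_length_s=1.0, overlap=0.0,
                                      folds=3, classifier_method="adaboost",
                                      n_learners_range=(10, 40))
        report = kfold_evaluate(recs, "heart", cfg, seed=2)
        assert report.fold_count == 3
        assert len(report.by_threshold) == 19
        assert report.per_fold["fold"].nunique() == 3
        assert ((report.by_threshold >= 0) & (report.by_threshold <= 1)).all().all()

    def test_deterministic_given_seed(self):
        recs = generate_dataset(4, 4, "heart", seed=5, duration_s=5)
        cfg = PipelineConfig.for_kind("heart", frame_length_s=1.0, overlap=0.0,
                                      folds=2, classifier_method="gentleboost",
                                      n_learners_range=(10, 30))
        a = kfold_evaluate(recs, "heart", cfg, seed=9)
        b = kfold_evaluate(recs, "heart", cfg, seed=9)
        assert a.by_threshold.equals(b.by_threshold)
        assert a.per_fold.equals(b.per_fold)

    def test_short_samples_are_excluded_not_counted(self):
        recs = generate_dataset(4, 4, "heart", seed=1, duration_s=6)
        short = generate_dataset(1, 0, "heart", seed=99, duration_s=1.5)[0]
        short.id = "too-short"
        cfg = PipelineConfig.for_kind("heart", frame_length_s=1.0, overlap=0.0,
                                      folds=2, classifier_method="adaboost",
                                      n_learners_range=(10, 30))
        report = kfold_evaluate(recs + [short], "heart", cfg, seed=2)
        assert "too-short" in report.excluded_ids
        # every fold's confusion total counts only the 8 usable samples
        per_fold_totals = (report.per_fold
                           .groupby("fold")[["tp", "tn", "fp", "fn"]].sum().sum(axis=1))
        assert (per_fold_totals == 4 * 19).all()

    def test_no_test_sample_frames_in_training(self):
        # leakage audit: fold test ids partition the sample ids, so a frame's
        # parent appears on exactly one side of each split
        labels = np.r_[np.zeros(6, dtype=int), np.ones(6, dtype=int)]
        ids = np.array([f"s{i}" for i in range(12)])
        folds = _stratified_folds(ids, labels, k=3, seed=0)
        for tr, te in folds:
            assert set(ids[tr]).isdisjoint(set(ids[te]))
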