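import itertools

import numpy as np
import pandas as pd
import pytest

from auscult import METHODS, predict_frames, select_model, train_candidate
from auscult.ensembles import ExhaustiveStump, _AdaBoost


def separable_blobs(n_per_class=40, margin=1.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([-2 - margin, 0], 0.5, size=(n_per_class, 2))
    b = rng.normal([2 + margin, 0], 0.5, size=(n_per_class, 2))
    X = np.vstack([a, b])
    y = np.r_[np.zeros(n_per_class, dtype=int), np.ones(n_per_class, dtype=int)]
    return X, y


def brute_force_stump_error(X, y_pm, w):
    """Minimum weighted 0-1 error over all stumps (exhaustive oracle)."""
    best = np.inf
    for j in range(X.shape[1]):
        for thr in np.r_[X[:, j] - 1e-9, X[:, j] + 1e-9]:
            for pol in (1, -1):
                pred = pol * np.where(X[:, j] > thr, 1.0, -1.0)
                best = min(best, float(w[pred != y_pm].sum()))
    return best


class TestTrainCandidate:
    @pytest.mark.parametrize("method", METHODS)
    def test_zero_training_error_on_separable_data(self, method):
        X, y = separable_blobs()
        model = train_candidate(X, y, method, seed=1, n_learners=60)
        assert np.mean(predict_frames(model, X) == y) == 1.0

    @pytest.mark.parametrize("method", METHODS)
    def test_deterministic_given_seed(self, method):
        X, y = separable_blobs(seed=3)
        grid = np.random.default_rng(9).normal(0, 3, size=(50, 2))
        p1 = predict_frames(train_candidate(X, y, method, seed=5), grid)
        p2 = predict_frames(train_candidate(X, y, method, seed=5), grid)
        assert np.array_equal(p1, p2)

    def test_rusboost_rounds_are_class_balanced(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 3))
        y = (rng.random(200) < 0.05).astype(int)
        y[:3] = 1  # guarantee a minority presence
        model = train_candidate(X, y, "rusboost", seed=2, n_learners=20)
        counts = model.estimator.round_class_counts_
        assert counts, "no boosting rounds recorded"
        assert all(neg == pos for neg, pos in counts)

    def test_single_class_labels_error(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            train_candidate(X, np.ones(10, dtype=int), "adaboost")

    def test_unknown_method(self):
        X, y = separable_blobs(5)
        with pytest.raises(ValueError):
            train_candidate(X, y, "randomforest")


class TestAdaBoostOracle:
    def test_first_stump_is_exhaustive_optimum(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 9))
            X = rng.integers(-4, 5, size=(n, 1)).astype(float)
            y = rng.choice([0, 1], size=n)
            if np.unique(y).size < 2:
                continue
            model = train_candidate(X, y, "adaboost", n_learners=1, max_depth=1)
            stump = model.estimator.learners_[0]
            y_pm = np.where(y == 1, 1.0, -1.0)
            w = np.full(n, 1.0 / n)
            err = float(w[stump.predict(X) != y_pm].sum())
            assert err == pytest.approx(brute_force_stump_error(X, y_pm, w), abs=1e-12)

    def test_single_stump_equivalence(self, rng):
        X = rng.standard_normal((30, 2))
        y = (X[:, 0] > 0.2).astype(int)
        model = train_candidate(X, y, "adaboost", n_learners=1, max_depth=1)
        stump = model.estimator.learners_[0]
        grid = rng.standard_normal((40, 2))
        expected = np.where(stump.predict(grid) > 0, 1, 0)
        assert np.array_equal(predict_frames(model, grid), expected)

    @pytest.mark.parametrize("method", ["adaboost", "gentleboost", "logitboost"])
    def test_training_error_nonincreasing_on_separable_data(self, method):
        X, y = separable_blobs(30, seed=6)
        model = train_candidate(X, y, method, seed=0, n_learners=25)
        errs = model.estimator.staged_train_error(X, y)
        assert np.all(np.diff(errs) <= 1e-12)

    def test_stump_minimizes_weighted_error_under_reweighting(self, rng):
        # optimality must hold for arbitrary weights, not just uniform ones
        for _ in range(20):
            n = int(rng.integers(3, 9))
            X = rng.integers(0, 5, size=(n, 2)).astype(float)
            y_pm = rng.choice([-1.0, 1.0], size=n)
            if np.unique(y_pm).size < 2:
                continue
            w = rng.random(n) + 0.05
            w /= w.sum()
            stump = ExhaustiveStump().fit(X, y_pm, w)
            err = float(w[stump.predict(X) != y_pm].sum())
            assert err <= brute_force_stump_error(X, y_pm, w) + 1e-12


class TestCommonContract:
    @pytest.mark.parametrize("method", METHODS)
    def test_swap_contract(self, method):
        X, y = separable_blobs(20, seed=8)
        model = train_candidate(X, y, method, seed=1, n_learners=10)
        pred = predict_frames(model, X)
        assert set(np.unique(pred)) <= {0, 1}
        score = model.decision_function(X)
        assert score.shape == (X.shape[0],)
        assert np.array_equal(pred, np.where(score > 0, 1, 0))

    def test_permuting_rows_permutes_predictions(self, rng):
        X, y = separable_blobs(20, seed=2)
        model = train_candidate(X, y, "gentleboost", seed=1, n_learners=10)
        perm = rng.permutation(X.shape[0])
        assert np.array_equal(predict_frames(model, X)[perm],
                              predict_frames(model, X[perm]))

    def test_schema_mismatch_raises(self):
        X, y = separable_blobs(10)
        df = pd.DataFrame(X, columns=["f0", "f1"])
        model = train_candidate(df, y, "bagging", seed=0, n_learners=5)
        with pytest.raises(ValueError):
            predict_frames(model, pd.DataFrame(X, columns=["f0", "other"]))
        with pytest.raises(ValueError):
            predict_frames(model, np.zeros((4, 3)))


class TestSelectModel:
    def test_trials_recorded_and_best_returned(self):
        X, y = separable_blobs(25, seed=1)
        model = select_model(X, y, n_trials=5, seed=3, n_bo_evals=2,
                             n_learners_range=(5, 20))
        assert len(model.trials) == 5
        assert model.objective == max(t["objective"] for t in model.trials)
        assert model.method == max(model.trials,
                                   key=lambda t: t["objective"])["method"]

    def test_single_trial(self):
        X, y = separable_blobs(25, seed=2)
        model = select_model(X, y, n_trials=1, seed=7, n_bo_evals=2,
                             n_learners_range=(5, 20))
        assert len(model.trials) == 1
        assert model.method in METHODS

    def test_separable_objective_high(self):
        X, y = separable_blobs(40, margin=2.0, seed=4)
        model = select_model(X, y, n_trials=2, seed=1, n_bo_evals=3,
                             n_learners_range=(10, 40))
        assert model.objective >= 0.95
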