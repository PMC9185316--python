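"""Ensemble classifiers for frame-level normal/abnormal decisions.

Five methods share one train/predict contract: bagging (bootstrap-aggregated
trees, via scikit-learn), discrete AdaBoost, GentleBoost, LogitBoost and
RUSBoost.  The boosting variants are implemented from their standard
additive-logistic-regression formulations:

* **AdaBoost** — exponential reweighting with vote weight
  ``alpha = 0.5 * ln((1 - err) / err)``.
* **GentleBoost** — Newton-step boosting: each round fits a regression tree
  to the +/-1 labels under the current exponential weights.
* **LogitBoost** — adaptive logistic regression: weighted least squares on
  the half working responses ``z = (y* - p) / (p (1 - p))``.
* **RUSBoost** — AdaBoost where each round's learner trains on a
  class-balanced random undersample (all minority samples plus an equal
  number of majority samples).

Depth-1 base learners for the AdaBoost family use an exhaustive
minimum-weighted-error decision stump; deeper learners are scikit-learn
trees fit with sample weights.  Classes are encoded internally as -1/+1
(abnormal = +1); the frame-level decision is ``score > 0``.

:func:`select_model` reproduces the randomized trial protocol: each trial
draws one of the five methods at random and tunes (n_learners, depth,
learning rate) by Bayesian optimization — a Gaussian-process surrogate with
expected-improvement acquisition — of the mean cross-validated accuracy; the
best trial's model is refit on the full training data and returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
import pandas as pd
from scipy import stats as sstats
from sklearn.ensemble import BaggingClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

__all__ = ["METHODS", "TrainedModel", "train_candidate", "select_model",
           "predict_frames", "ExhaustiveStump"]

METHODS = ("bagging", "adaboost", "gentleboost", "logitboost", "rusboost")

_ALPHA_CAP = 10.0  # vote weight assigned to a zero-error learner


class ExhaustiveStump:
    """Depth-1 axis-aligned classifier minimizing weighted 0-1 error.

    Scans every feature and every midpoint threshold in both polarities and
    keeps the split with the smallest weighted misclassification; ties break
    toward the lowest feature index, then the smallest threshold.  Predicts
    -1/+1.
    """

    feature_: int
    threshold_: float
    polarity_: int  # +1: predict +1 where x > threshold

    def fit(self, X: np.ndarray, y: np.ndarray, sample_weight: np.ndarray):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        w = np.asarray(sample_weight, dtype=float)
        w = w / w.sum()
        best = (np.inf, 0, -np.inf, 1)
        for j in range(X.shape[1]):
            xj = X[:, j]
            order = np.argsort(xj, kind="mergesort")
            xs, ys, ws = xj[order], y[order], w[order]
            # weighted error of "predict +1 where x > cut" for every cut,
            # via prefix sums: below-cut positives + above-cut negatives
            cum_pos = np.concatenate([[0.0], np.cumsum(ws * (ys > 0))])
            cum_neg = np.concatenate([[0.0], np.cumsum(ws * (ys < 0))])
            total_neg = cum_neg[-1]
            errs = cum_pos + (total_neg - cum_neg)  # cut after index i-1
            # valid cut positions: before all data, or between distinct values
            distinct = np.concatenate([[True], xs[1:] > xs[:-1]])
            thrs = np.concatenate([[xs[0] - 1.0], (xs[:-1] + xs[1:]) / 2.0])
            for polarity in (1, -1):
                e = errs if polarity == 1 else 1.0 - errs
                e = e[:-1]  # cut after the last sample predicts one class; kept via polarity of cut 0
                valid = np.flatnonzero(distinct)
                i = valid[int(np.argmin(e[valid]))]
                if e[i] < best[0] - 1e-15:
                    best = (float(e[i]), j, float(thrs[i]), polarity)
        _, self.feature_, self.threshold_, self.polarity_ = best
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        x = np.asarray(X, dtype=float)[:, self.feature_]
        return self.polarity_ * np.where(x > self.threshold_, 1.0, -1.0)


def _check_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes in y, got {classes.size}")
    ypm = np.where(y == classes.max(), 1.0, -1.0)  # abnormal/1 -> +1
    return X, ypm, classes


class _BoostBase:
    """Shared fit/predict plumbing for the boosting variants."""

    def __init__(self, n_learners=100, max_depth=1, learning_rate=1.0, seed=0):
        if n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        self.n_learners = int(n_learners)
        self.max_depth = int(max_depth)
        self.learning_rate = float(learning_rate)
        self.seed = int(seed)
        self.learners_: list = []
        self.classes_: np.ndarray | None = None

    def fit(self, X, y):
        X, ypm, classes = _check_xy(X, y)
        self.classes_ = classes
        self._fit_pm(X, ypm, np.random.default_rng(self.seed))
        return self

    def decision_function(self, X) -> np.ndarray:
        return self._score(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        lo, hi = self.classes_
        return np.where(score > 0, hi, lo)

    def staged_train_error(self, X, y) -> np.ndarray:
        """Training 0-1 error after each boosting round."""
        X, ypm, _ = _check_xy(X, y)
        errs = []
        for t in range(1, len(self.learners_) + 1):
            s = self._score(X, upto=t)
            errs.append(float(np.mean(np.where(s > 0, 1.0, -1.0) != ypm)))
        return np.asarray(errs)


class _AdaBoost(_BoostBase):
    """Discrete AdaBoost with exponential reweighting."""

    resample_balanced = False  # RUSBoost toggles this

    def _make_learner(self):
        if self.max_depth == 1:
            return ExhaustiveStump()
        return DecisionTreeClassifier(max_depth=self.max_depth, random_state=0)

    def _fit_pm(self, X, y, rng):
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        self.learners_, self.alphas_ = [], []
        self.round_class_counts_: list[tuple[int, int]] = []
        for _ in range(self.n_learners):
            learner = self._make_learner()
            if self.resample_balanced:
                idx = self._balanced_indices(y, rng)
                self.round_class_counts_.append(
                    (int(np.sum(y[idx] < 0)), int(np.sum(y[idx] > 0))))
                wfit = w[idx] / w[idx].sum()
                if isinstance(learner, ExhaustiveStump):
                    learner.fit(X[idx], y[idx], wfit)
                else:
                    learner.fit(X[idx], y[idx], sample_weight=wfit)
            else:
                if isinstance(learner, ExhaustiveStump):
                    learner.fit(X, y, w)
                else:
                    learner.fit(X, y, sample_weight=w)
            pred = np.sign(learner.predict(X)).astype(float)
            pred[pred == 0] = 1.0
            err = float(w[pred != y].sum())
            if err <= 1e-12:
                self.learners_.append(learner)
                self.alphas_.append(_ALPHA_CAP)
                break
            if err >= 0.5:
                break  # learner no better than chance under current weights
            alpha = self.learning_rate * 0.5 * np.log((1.0 - err) / err)
            self.learners_.append(learner)
            self.alphas_.append(alpha)
            w *= np.exp(-alpha * y * pred)
            w /= w.sum()
        if not self.learners_:  # keep the contract: at least one learner
            learner = self._make_learner()
            if isinstance(learner, ExhaustiveStump):
                learner.fit(X, y, np.full(n, 1.0 / n))
            else:
                learner.fit(X, y, sample_weight=np.full(n, 1.0 / n))
            self.learners_.append(learner)
            self.alphas_.append(1.0)

    @staticmethod
    def _balanced_indices(y, rng) -> np.ndarray:
        pos = np.flatnonzero(y > 0)
        neg = np.flatnonzero(y < 0)
        minority, majority = (pos, neg) if pos.size <= neg.size else (neg, pos)
        picked = rng.choice(majority, size=minority.size, replace=False)
        return np.concatenate([minority, picked])

    def _score(self, X, upto=None):
        upto = len(self.learners_) if upto is None else upto
        s = np.zeros(X.shape[0])
        for alpha, learner in zip(self.alphas_[:upto], self.learners_[:upto]):
            pred = np.sign(learner.predict(X)).astype(float)
            pred[pred == 0] = 1.0
            s += alpha * pred
        return s


class _RUSBoost(_AdaBoost):
    """AdaBoost over per-round class-balanced random undersamples."""

    resample_balanced = True


class _GentleBoost(_BoostBase):
    """Newton-step boosting with weighted regression trees on +/-1 labels."""

    def _fit_pm(self, X, y, rng):
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        self.learners_ = []
        for t in range(self.n_learners):
            tree = DecisionTreeRegressor(max_depth=self.max_depth, random_state=0)
            tree.fit(X, y, sample_weight=w)
            h = tree.predict(X)
            self.learners_.append(tree)
            w *= np.exp(-self.learning_rate * y * h)
            total = w.sum()
            if not np.isfinite(total) or total <= 0:
                break
            w /= total

    def _score(self, X, upto=None):
        upto = len(self.learners_) if upto is None else upto
        s = np.zeros(X.shape[0])
        for tree in self.learners_[:upto]:
            s += self.learning_rate * tree.predict(X)
        return s


class _LogitBoost(_BoostBase):
    """Adaptive logistic regression via weighted least squares on working responses."""

    _Z_MAX = 4.0
    _P_EPS = 1e-8

    def _fit_pm(self, X, y, rng):
        n = X.shape[0]
        ystar = (y + 1.0) / 2.0  # {0, 1}
        F = np.zeros(n)
        p = np.full(n, 0.5)
        self.learners_ = []
        for t in range(self.n_learners):
            w = np.clip(p * (1.0 - p), self._P_EPS, None)
            z = np.clip((ystar - p) / w, -self._Z_MAX, self._Z_MAX)
            tree = DecisionTreeRegressor(max_depth=self.max_depth, random_state=0)
            tree.fit(X, z, sample_weight=w / w.sum())
            h = tree.predict(X)
            F += 0.5 * self.learning_rate * h
            p = 1.0 / (1.0 + np.exp(-2.0 * np.clip(F, -30, 30)))
            self.learners_.append(tree)

    def _score(self, X, upto=None):
        upto = len(self.learners_) if upto is None else upto
        s = np.zeros(X.shape[0])
        for tree in self.learners_[:upto]:
            s += 0.5 * self.learning_rate * tree.predict(X)
        return s


class _BaggingWrapper:
    """Bootstrap-aggregated trees behind the common contract."""

    def __init__(self, n_learners=100, max_depth=None, learning_rate=None, seed=0):
        self.n_learners = int(n_learners)
        self.max_depth = max_depth
        self.seed = int(seed)
        self._clf = BaggingClassifier(
            estimator=DecisionTreeClassifier(max_depth=max_depth, random_state=0),
            n_estimators=self.n_learners, random_state=self.seed)
        self.classes_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if np.unique(y).size != 2:
            raise ValueError("need exactly 2 classes in y")
        self._clf.fit(X, y)
        self.classes_ = self._clf.classes_
        return self

    def decision_function(self, X) -> np.ndarray:
        proba = self._clf.predict_proba(np.asarray(X, dtype=float))
        return proba[:, 1] - proba[:, 0]  # majority-vote margin

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        lo, hi = self.classes_
        return np.where(score > 0, hi, lo)


_DEFAULT_DEPTH = {"bagging": None, "adaboost": 1, "gentleboost": 2,
                  "logitboost": 2, "rusboost": 1}


@dataclass
class TrainedModel:
    """A fitted frame-level classifier plus its selection bookkeeping."""

    method: str
    estimator: object
    n_learners: int
    max_depth: int | None
    learning_rate: float
    trial_seed: int
    objective: float = float("nan")
    feature_names: tuple[str, ...] | None = None
    trials: list = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        return predict_frames(self, X)

    def decision_function(self, X) -> np.ndarray:
        X = _coerce_features(self, X)
        return self.estimator.decision_function(X)


def _coerce_features(model: TrainedModel, X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if model.feature_names is not None:
            missing = [c for c in model.feature_names if c not in X.columns]
            if missing:
                raise ValueError(f"feature columns missing: {missing}")
            X = X.loc[:, list(model.feature_names)]
        return X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if model.feature_names is not None and X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} feature columns, got {X.shape[1]}")
    return X


def train_candidate(features, labels, method: str, seed: int = 0,
                    n_learners: int = 100, max_depth: int | None = None,
                    learning_rate: float = 0.5) -> TrainedModel:
    """Fit one ensemble of the given method with fixed hyperparameters.

    ``features`` may be an ndarray or a DataFrame (column names become the
    prediction schema); ``labels`` must contain both classes.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    names = None
    if isinstance(features, pd.DataFrame):
        names = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    depth = _DEFAULT_DEPTH[method] if max_depth is None else int(max_depth)
    cls = {"bagging": _BaggingWrapper, "adaboost": _AdaBoost,
           "gentleboost": _GentleBoost, "logitboost": _LogitBoost,
           "rusboost": _RUSBoost}[method]
    est = cls(n_learners=n_learners, max_depth=depth,
              learning_rate=learning_rate, seed=seed)
    est.fit(X, y)
    return TrainedModel(method=method, estimator=est, n_learners=n_learners,
                        max_depth=depth, learning_rate=learning_rate,
                        trial_seed=seed, feature_names=names)


def predict_frames(model: TrainedModel, features) -> np.ndarray:
    """One deterministic label per frame; columns must match the training schema."""
    X = _coerce_features(model, features)
    return model.estimator.predict(X)


def _cv_accuracy(X, y, method, params, seed, cv=3) -> float:
    skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed % (2**31))
    accs = []
    for tr, te in skf.split(X, y):
        if np.unique(y[tr]).size < 2:
            continue
        m = train_candidate(X[tr], y[tr], method, seed=seed, **params)
        accs.append(float(np.mean(predict_frames(m, X[te]) == y[te])))
    return float(np.mean(accs)) if accs else 0.0


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return sigma * (z * sstats.norm.cdf(z) + sstats.norm.pdf(z))


def _bayes_opt(X, y, method, seed, n_evals, n_learners_range, depth_range,
               lr_range, cv):
    """Maximize CV accuracy over (n_learners, depth, lr) with a GP surrogate."""
    rng = np.random.default_rng(seed)

    def decode(u):
        nl = int(round(n_learners_range[0]
                       + u[0] * (n_learners_range[1] - n_learners_range[0])))
        dp = int(round(depth_range[0] + u[1] * (depth_range[1] - depth_range[0])))
        lr = float(lr_range[0] * (lr_range[1] / lr_range[0]) ** u[2])  # log scale
        return {"n_learners": nl, "max_depth": dp, "learning_rate": lr}

    n_init = min(5, n_evals)
    points, scores = [], []
    for _ in range(n_init):
        u = rng.random(3)
        points.append(u)
        scores.append(_cv_accuracy(X, y, method, decode(u), seed, cv))
    kernel = Matern(nu=2.5, length_scale=0.3) + WhiteKernel(1e-4)
    while len(points) < n_evals:
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      random_state=seed % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.asarray(points), np.asarray(scores))
        cand = rng.random((128, 3))
        mu, sd = gp.predict(cand, return_std=True)
        u = cand[int(np.argmax(_expected_improvement(mu, sd, max(scores))))]
        points.append(u)
        scores.append(_cv_accuracy(X, y, method, decode(u), seed, cv))
    best = int(np.argmax(scores))
    return decode(points[best]), float(scores[best])


def select_model(features, labels, n_trials: int = 5, seed: int = 0,
                 n_bo_evals: int = 20,
                 n_learners_range: tuple[int, int] = (50, 500),
                 depth_range: tuple[int, int] = (1, 4),
                 lr_range: tuple[float, float] = (0.01, 1.0),
                 cv: int = 3) -> TrainedModel:
    """Randomized trials: draw a method per trial, tune it by Bayesian
    optimization of cross-validated accuracy, keep the best observation.

    The returned model is refit on all the training data with the winning
    trial's method and hyperparameters; ``model.trials`` records every
    trial's method, parameters and objective.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    names = tuple(features.columns) if isinstance(features, pd.DataFrame) else None
    X = (features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame)
         else np.asarray(features, dtype=float))
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)

    trials = []
    for t in range(n_trials):
        method = str(rng.choice(METHODS))
        tseed = int(rng.integers(0, 2**31 - 1))
        params, score = _bayes_opt(X, y, method, tseed, n_bo_evals,
                                   n_learners_range, depth_range, lr_range, cv)
        trials.append({"trial": t, "method": method, "seed": tseed,
                       "params": params, "objective": score})
    best = max(trials, key=lambda d: d["objective"])
    model = train_candidate(X, y, best["method"], seed=best["seed"],
                            **best["params"])
    model.objective = best["objective"]
    model.trials = trials
    model.feature_names = names
    return model
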