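"""Frame-vote aggregation and k-fold evaluation metrics.

A sample is called abnormal when the fraction of its frames classified
abnormal *strictly exceeds* the voting threshold; the sweep reports every
threshold on the 5%..95% grid (step 5%, 19 values).  Metrics follow the
standard confusion-matrix definitions:

    accuracy    = (TP + TN) / (TP + FN + FP + TN)
    specificity = TN / (FP + TN)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    F1          = 2 * sensitivity * precision / (sensitivity + precision)

with degenerate denominators mapped to 0.  K-fold evaluation is stratified
at the *sample* level — frames of one recording never straddle folds — and
the final report is the unweighted mean of per-fold metrics per threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .audio_io import AudioRecording, Label, SoundKind
from .config import PipelineConfig
from .ensembles import predict_frames, select_model, train_candidate
from .pipeline import features_table

__all__ = ["THRESHOLD_GRID", "VoteDecision", "ConfusionCounts", "MetricsReport",
           "vote_sample", "compute_metrics", "sweep_thresholds", "kfold_evaluate"]

logger = logging.getLogger(__name__)

#: Voting-ratio grid: 5%, 10%, ..., 95%.
THRESHOLD_GRID = tuple(np.round(np.arange(1, 20) * 0.05, 2))

METRIC_NAMES = ("accuracy", "specificity", "sensitivity", "precision", "f1")


@dataclass(frozen=True)
class VoteDecision:
    """Sample-level vote outcome."""

    parent_id: str
    n_frames: int
    n_abnormal_frames: int
    threshold: float
    decision: Label

    @property
    def abnormal_fraction(self) -> float:
        return self.n_abnormal_frames / self.n_frames


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Per-threshold (and optionally per-fold) evaluation metrics."""

    by_threshold: pd.DataFrame          # index: threshold; columns: metrics
    per_fold: pd.DataFrame | None = None  # columns: fold, threshold, metrics
    fold_count: int = 1
    excluded_ids: tuple[str, ...] = ()

    def at_threshold(self, threshold: float) -> pd.Series:
        return self.by_threshold.loc[round(threshold, 2)]


def vote_sample(frame_labels, threshold: float, parent_id: str = "") -> VoteDecision:
    """Vote one sample abnormal iff its abnormal-frame fraction > threshold."""
    labels = np.asarray(frame_labels).astype(int)
    if labels.size == 0:
        raise ValueError("frame_labels must be non-empty")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    n_abn = int(labels.sum())
    decision = Label.ABNORMAL if n_abn / labels.size > threshold else Label.NORMAL
    return VoteDecision(parent_id=parent_id, n_frames=int(labels.size),
                        n_abnormal_frames=n_abn, threshold=threshold,
                        decision=decision)


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """The five metrics from confusion counts; degenerate denominators -> 0."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("need at least one evaluated sample")

    def ratio(num, den, name):
        if den == 0:
            logger.warning("degenerate denominator for %s; reporting 0", name)
            return 0.0
        return num / den

    se = ratio(tp, tp + fn, "sensitivity")
    pr = ratio(tp, tp + fp, "precision")
    f1 = 0.0 if se + pr == 0 else 2 * se * pr / (se + pr)
    return {
        "accuracy": (tp + tn) / counts.total,
        "specificity": ratio(tn, fp + tn, "specificity"),
        "sensitivity": se,
        "precision": pr,
        "f1": f1,
    }


def sweep_thresholds(per_sample_frame_labels, true_labels,
                     thresholds=THRESHOLD_GRID) -> pd.DataFrame:
    """Confusion counts and metrics for every voting threshold on the grid.

    ``per_sample_frame_labels`` is one binary frame-label sequence per sample;
    ``true_labels`` the aligned sample-level truth (1 = abnormal).
    """
    if len(per_sample_frame_labels) != len(true_labels):
        raise ValueError("per-sample frame labels and true labels misaligned")
    truth = np.asarray(true_labels).astype(int)
    rows = []
    for thr in thresholds:
        pred = np.array([
            1 if vote_sample(fl, thr).decision is Label.ABNORMAL else 0
            for fl in per_sample_frame_labels])
        counts = ConfusionCounts(tp=int(np.sum((pred == 1) & (truth == 1))),
                                 tn=int(np.sum((pred == 0) & (truth == 0))),
                                 fp=int(np.sum((pred == 1) & (truth == 0))),
                                 fn=int(np.sum((pred == 0) & (truth == 1))))
        row = {"threshold": round(float(thr), 2), "tp": counts.tp, "tn": counts.tn,
               "fp": counts.fp, "fn": counts.fn}
        row.update(compute_metrics(counts))
        rows.append(row)
    return pd.DataFrame(rows).set_index("threshold")


def _stratified_folds(ids, labels, k, seed, max_retries=5):
    """Sample-level stratified folds; every fold must contain both classes."""
    y = np.asarray(labels)
    for attempt in range(max_retries):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=(seed + attempt) % (2**31))
        folds = list(skf.split(np.zeros(len(y)), y))
        ok = all(np.unique(y[te]).size == 2 and np.unique(y[tr]).size == 2
                 for tr, te in folds)
        if ok:
            if attempt:
                logger.info("fold split reseeded %d time(s)", attempt)
            return folds
    raise ValueError("could not build folds with both classes present in "
                     f"every fold after {max_retries} attempts")


def kfold_evaluate(recordings: list[AudioRecording], kind: str | SoundKind,
                   config: PipelineConfig | None = None, seed: int = 0) -> MetricsReport:
    """Sample-level stratified k-fold evaluation of the full pipeline.

    Per fold: extract features from the training recordings' frames, fit the
    configured classifier, predict the held-out recordings' frames, vote at
    every grid threshold, and compute metrics; the report averages metrics
    over folds (unweighted).  Recordings excluded by the minimum-frame rule
    never enter any fold.
    """
    kind = SoundKind(kind)
    config = config or PipelineConfig.for_kind(kind)
    config.validate()

    table, excluded = features_table(recordings, config)
    if table.empty:
        raise ValueError("no usable recordings after segmentation")
    sample_ids = table["parent_id"].unique()
    sample_labels = (table.drop_duplicates("parent_id")
                     .set_index("parent_id")["label"].loc[sample_ids].to_numpy())

    folds = _stratified_folds(sample_ids, sample_labels, config.folds, seed)
    feat_cols = [c for c in table.columns
                 if c not in ("parent_id", "frame_idx", "label")]

    rng = np.random.default_rng(seed)
    fold_frames = []
    for fold_idx, (tr, te) in enumerate(folds):
        tr_ids, te_ids = set(sample_ids[tr]), set(sample_ids[te])
        train_tab = table[table["parent_id"].isin(tr_ids)]
        test_tab = table[table["parent_id"].isin(te_ids)]
        fseed = int(rng.integers(0, 2**31 - 1))

        if config.classifier_method == "auto":
            model = select_model(train_tab[feat_cols], train_tab["label"].to_numpy(),
                                 n_trials=config.classifier_trials, seed=fseed,
                                 n_bo_evals=config.bo_evals,
                                 n_learners_range=config.n_learners_range,
                                 cv=config.inner_cv)
        else:
            model = train_candidate(train_tab[feat_cols],
                                    train_tab["label"].to_numpy(),
                                    config.classifier_method, seed=fseed,
                                    n_learners=config.n_learners_range[1])
        pred = predict_frames(model, test_tab[feat_cols])

        grouped = test_tab.assign(pred=pred).groupby("parent_id", sort=True)
        per_sample = [g["pred"].to_numpy() for _, g in grouped]
        truths = [int(g["label"].iloc[0]) for _, g in grouped]
        sweep = sweep_thresholds(per_sample, truths).reset_index()
        sweep.insert(0, "fold", fold_idx)
        fold_frames.append(sweep)

    per_fold = pd.concat(fold_frames, ignore_index=True)
    by_threshold = (per_fold.groupby("threshold")[list(METRIC_NAMES)]
                    .mean().sort_index())
    return MetricsReport(by_threshold=by_threshold, per_fold=per_fold,
                         fold_count=config.folds, excluded_ids=tuple(excluded))
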