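"""Model/Results facade over the classification pipeline.

``AuscultationClassifier`` is built from a labeled corpus of recordings plus
a pipeline configuration; ``fit()`` runs the stratified k-fold experiment —
band filter, overlapping segmentation, PCA-residual denoising, 27-feature
extraction, ensemble training with randomized trial selection, frame voting
— and returns an ``AuscultationResults`` carrying the per-threshold and
per-fold metrics with a printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio_io import AudioRecording, SoundKind
from .config import PipelineConfig
from .vote_eval import MetricsReport, kfold_evaluate

__all__ = ["AuscultationClassifier", "AuscultationResults"]


class AuscultationClassifier:
    """K-fold-evaluated cardiopulmonary sound classifier.

    Parameters
    ----------
    recordings : list of AudioRecording
        Labeled heart or lung recordings (one sound kind per model).
    config : PipelineConfig, optional
        Pipeline settings; defaults to the best-performing grid point for
        the corpus's sound kind (heart: 2 s frames / 20% overlap / 5 folds;
        lung: 5 s frames / 50% overlap / 3 folds).
    """

    def __init__(self, recordings: list[AudioRecording],
                 config: PipelineConfig | None = None):
        if not recordings:
            raise ValueError("need at least one recording")
        kinds = {r.sound_kind for r in recordings}
        if len(kinds) != 1:
            raise ValueError("all recordings must share one sound kind")
        self.sound_kind: SoundKind = kinds.pop()
        self.recordings = list(recordings)
        self.config = config or PipelineConfig.for_kind(self.sound_kind)
        self.config.validate()

    @classmethod
    def from_recordings(cls, recordings, **config_overrides) -> "AuscultationClassifier":
        kind = recordings[0].sound_kind if recordings else SoundKind.HEART
        return cls(recordings, PipelineConfig.for_kind(kind, **config_overrides))

    def fit(self, seed: int = 0) -> "AuscultationResults":
        """Run the k-fold experiment; deterministic given ``seed``."""
        report = kfold_evaluate(self.recordings, self.sound_kind,
                                self.config, seed=seed)
        return AuscultationResults(model=self, report=report, seed=seed)


@dataclass
class AuscultationResults:
    """Metrics of one fitted k-fold experiment."""

    model: AuscultationClassifier
    report: MetricsReport
    seed: int

    @property
    def metrics(self) -> pd.DataFrame:
        """Fold-averaged metrics per voting threshold."""
        return self.report.by_threshold

    @property
    def fold_metrics(self) -> pd.DataFrame:
        return self.report.per_fold

    def at_threshold(self, threshold: float) -> pd.Series:
        return self.report.at_threshold(threshold)

    @property
    def best_threshold(self) -> float:
        """Voting threshold maximizing fold-averaged accuracy (ties: lowest)."""
        acc = self.metrics["accuracy"]
        return float(acc.index[int(np.argmax(acc.to_numpy()))])

    def plot_thresholds(self, ax=None):
        """Plot the fold-averaged metric curves against the voting threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for name in ("accuracy", "sensitivity", "specificity", "f1"):
            ax.plot(self.metrics.index, self.metrics[name], marker="o",
                    markersize=3, label=name)
        ax.set_xlabel("voting threshold")
        ax.set_ylabel("score")
        ax.set_ylim(-0.02, 1.02)
        ax.legend(frameon=False)
        ax.set_title(f"{self.model.config.sound_kind} sounds, "
                     f"{self.report.fold_count}-fold mean")
        return ax

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Cardiopulmonary sound classification — k-fold voting results",
            "=" * 62,
            f"sound kind:      {cfg.sound_kind}",
            f"frame length:    {cfg.frame_length_s} s, overlap {cfg.overlap:.0%}",
            f"PCA threshold:   {cfg.pca_threshold} ({cfg.pca_subwindows} sub-windows)",
            f"classifier:      {cfg.classifier_method} "
            f"({cfg.classifier_trials} trials)",
            f"folds:           {self.report.fold_count}   seed: {self.seed}",
            f"excluded samples: {len(self.report.excluded_ids)}",
            "-" * 62,
            "threshold  accuracy  sensitivity  specificity  precision     f1",
        ]
        for thr, row in self.metrics.iterrows():
            lines.append(f"{thr:9.2f}  {row['accuracy']:8.3f}  "
                         f"{row['sensitivity']:11.3f}  {row['specificity']:11.3f}  "
                         f"{row['precision']:9.3f}  {row['f1']:5.3f}")
        best = self.best_threshold
        row = self.at_threshold(best)
        lines += ["-" * 62,
                  f"best accuracy {row['accuracy']:.3f} at voting threshold "
                  f"{best:.0%}"]
        return "\n".join(lines)
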