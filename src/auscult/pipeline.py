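"""Per-recording feature pipeline: filter -> segment -> PCA residual -> features."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .audio_io import AudioRecording, Label, SoundKind, heart_filter, lung_filter
from .config import PipelineConfig
from .features import FEATURE_NAMES, feature_vector
from .pca_residual import pca_residual
from .segmentation import segment

__all__ = ["features_table", "recording_features"]


def _apply_band_filter(rec: AudioRecording) -> AudioRecording:
    if rec.sound_kind is SoundKind.HEART:
        return heart_filter(rec)
    if rec.sound_kind is SoundKind.LUNG:
        return lung_filter(rec)
    return rec


def recording_features(rec: AudioRecording, config: PipelineConfig) -> pd.DataFrame | None:
    """The frame-feature rows of one recording, or None if it is excluded.

    Columns: parent_id, frame_idx, label (1 = abnormal), then the 27 named
    features of each PCA-residual frame.
    """
    filtered = _apply_band_filter(rec) if config.apply_filter else rec
    fs = segment(filtered, config.frame_length_s, config.overlap)
    if fs.excluded:
        return None
    rows = []
    for idx, frame in enumerate(fs.frames):
        res = pca_residual(frame, rate=rec.rate, threshold=config.pca_threshold,
                           n_subwindows=config.pca_subwindows)
        fv = feature_vector(res, rec.rate)
        rows.append([rec.id, idx, 1 if rec.label is Label.ABNORMAL else 0,
                     *fv.values])
    return pd.DataFrame(rows, columns=["parent_id", "frame_idx", "label",
                                       *FEATURE_NAMES])


def features_table(recordings: list[AudioRecording],
                   config: PipelineConfig) -> tuple[pd.DataFrame, list[str]]:
    """Feature rows for a corpus plus the ids excluded by the min-frame rule."""
    parts, excluded = [], []
    for rec in recordings:
        tab = recording_features(rec, config)
        if tab is None:
            excluded.append(rec.id)
        else:
            parts.append(tab)
    table = (pd.concat(parts, ignore_index=True) if parts
             else pd.DataFrame(columns=["parent_id", "frame_idx", "label",
                                        *FEATURE_NAMES]))
    return table, excluded
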