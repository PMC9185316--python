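"""Overlapping fixed-length framing of recordings.

A recording of length ``L`` seconds cut into frames of ``F`` seconds at hop
``H = F * (1 - overlap)`` yields ``floor((L - F) / H) + 1`` frames (when
``L >= F``); trailing samples that do not fill a frame are dropped.  A
recording producing fewer than two frames is *excluded* — it must not enter
training or fold counts, and the exclusion is recorded rather than silently
applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audio_io import AudioRecording

__all__ = ["FrameSet", "segment", "HEART_FRAME_GRID_S", "LUNG_FRAME_GRID_S",
           "OVERLAP_GRID"]

HEART_FRAME_GRID_S = (1.0, 1.5, 2.0)
LUNG_FRAME_GRID_S = (3.0, 4.0, 5.0)
OVERLAP_GRID = (0.0, 0.2, 0.5)

_MIN_FRAMES = 2


@dataclass
class FrameSet:
    """Frames cut from one recording plus the segmentation parameters.

    ``excluded`` is True when the parent yielded fewer than two frames; in
    that case ``frames`` is empty and the parent must not be counted as a
    sample downstream.
    """

    frames: list[np.ndarray]
    frame_length_s: float
    overlap: float
    parent_id: str
    rate: int
    start_indices: list[int] = field(default_factory=list)
    excluded: bool = False

    @property
    def hop_s(self) -> float:
        return self.frame_length_s * (1.0 - self.overlap)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def segment(rec: AudioRecording, frame_length_s: float, overlap: float) -> FrameSet:
    """Cut ``rec`` into overlapping frames.

    Frame start times are quantized to whole samples by round-half-even of
    ``k * hop_s * rate``; each frame has exactly ``round(frame_length_s *
    rate)`` samples.

    Raises
    ------
    ValueError
        If ``overlap`` is outside [0, 1) or ``frame_length_s`` <= 0.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError(f"overlap must lie in [0, 1), got {overlap}")
    if frame_length_s <= 0:
        raise ValueError(f"frame_length_s must be positive, got {frame_length_s}")

    n = rec.samples.size
    flen = int(round(frame_length_s * rec.rate))
    hop_s = frame_length_s * (1.0 - overlap)

    frames: list[np.ndarray] = []
    starts: list[int] = []
    k = 0
    while True:
        start = int(np.round(k * hop_s * rec.rate))  # round-half-even
        if start + flen > n:
            break
        frames.append(rec.samples[start:start + flen].copy())
        starts.append(start)
        k += 1

    if len(frames) < _MIN_FRAMES:
        return FrameSet(frames=[], frame_length_s=frame_length_s, overlap=overlap,
                        parent_id=rec.id, rate=rec.rate, start_indices=[],
                        excluded=True)
    return FrameSet(frames=frames, frame_length_s=frame_length_s, overlap=overlap,
                    parent_id=rec.id, rate=rec.rate, start_indices=starts)
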