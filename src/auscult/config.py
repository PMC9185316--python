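"""Pipeline configuration with grid enforcement.

The segmentation grids (frame lengths 1/1.5/2 s for heart, 3/4/5 s for lung;
overlaps 0/20/50%) and the PCA contribution range [0.85, 0.95] are enforced
at validation time so experiments stay on the study grids by default; set
``allow_off_grid=True`` to explore outside them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .audio_io import SoundKind
from .segmentation import HEART_FRAME_GRID_S, LUNG_FRAME_GRID_S, OVERLAP_GRID

__all__ = ["PipelineConfig"]

_CLASSIFIER_CHOICES = ("auto", "bagging", "adaboost", "gentleboost",
                       "logitboost", "rusboost")


@dataclass
class PipelineConfig:
    sound_kind: str = "heart"
    frame_length_s: float = 2.0
    overlap: float = 0.2
    apply_filter: bool = True
    pca_threshold: float = 0.95
    pca_subwindows: int = 20
    classifier_method: str = "auto"
    classifier_trials: int = 5
    bo_evals: int = 20
    n_learners_range: tuple[int, int] = (50, 500)
    inner_cv: int = 3
    folds: int = 5
    allow_off_grid: bool = False

    @classmethod
    def for_kind(cls, kind: str | SoundKind, **overrides) -> "PipelineConfig":
        """Defaults per sound kind: heart = 2 s / 20% / 5 folds,
        lung = 5 s / 50% / 3 folds (the best-performing settings)."""
        kind = SoundKind(kind)
        base = (dict(sound_kind="heart", frame_length_s=2.0, overlap=0.2, folds=5)
                if kind is SoundKind.HEART
                else dict(sound_kind="lung", frame_length_s=5.0, overlap=0.5, folds=3))
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "n_learners_range" in raw:
            raw["n_learners_range"] = tuple(raw["n_learners_range"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        kind = SoundKind(self.sound_kind)
        grid = HEART_FRAME_GRID_S if kind is SoundKind.HEART else LUNG_FRAME_GRID_S
        if not self.allow_off_grid:
            if self.frame_length_s not in grid:
                raise ValueError(
                    f"frame_length_s={self.frame_length_s} off the {kind.value} "
                    f"grid {grid} (set allow_off_grid=True to override)")
            if self.overlap not in OVERLAP_GRID:
                raise ValueError(
                    f"overlap={self.overlap} off the grid {OVERLAP_GRID} "
                    "(set allow_off_grid=True to override)")
            if not 0.85 <= self.pca_threshold <= 0.95:
                raise ValueError(
                    f"pca_threshold={self.pca_threshold} outside [0.85, 0.95] "
                    "(set allow_off_grid=True to override)")
        else:
            if not 0 <= self.overlap < 1:
                raise ValueError("overlap must lie in [0, 1)")
            if not 0 < self.pca_threshold <= 1:
                raise ValueError("pca_threshold must lie in (0, 1]")
        if self.frame_length_s <= 0:
            raise ValueError("frame_length_s must be positive")
        if self.classifier_method not in _CLASSIFIER_CHOICES:
            raise ValueError(f"classifier_method must be one of {_CLASSIFIER_CHOICES}")
        if self.folds < 2 or self.inner_cv < 2:
            raise ValueError("folds and inner_cv must be >= 2")
        if self.classifier_trials < 1 or self.bo_evals < 1:
            raise ValueError("classifier_trials and bo_evals must be >= 1")
        if self.pca_subwindows < 1:
            raise ValueError("pca_subwindows must be >= 1")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["n_learners_range"] = list(self.n_learners_range)
        return d
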