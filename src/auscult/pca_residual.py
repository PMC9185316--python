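"""PCA-residual (difference-signal) denoising of sound frames.

Each frame is reshaped into a matrix of consecutive equal sub-windows, the
leading principal components — which capture the repeating heartbeat or
breath template that dominates the frame's variance — are removed, and the
residual is mapped back to a same-length difference signal.  The number of
removed components is the smallest count whose cumulative explained-variance
fraction reaches the contribution threshold (default 0.95, configurable in
[0.85, 0.95]): abnormal transients such as murmurs or crackles survive in the
residual while the dominant periodic structure is subtracted.

The sub-window embedding is one concrete choice of how a 1-D frame becomes a
PCA-able matrix; it is isolated here so an alternative embedding (e.g. frames
across a recording as observations) can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResidualFrame", "choose_num_components", "pca_residual",
           "DEFAULT_THRESHOLD", "DEFAULT_SUBWINDOWS"]

DEFAULT_THRESHOLD = 0.95
DEFAULT_SUBWINDOWS = 20


@dataclass
class ResidualFrame:
    """A frame's PCA difference signal with removed-variance bookkeeping."""

    residual: np.ndarray
    removed_fraction: float
    n_components_removed: int
    contribution_threshold: float

    @property
    def n_samples(self) -> int:
        return self.residual.size


def choose_num_components(explained_fractions, threshold: float) -> int:
    """Smallest k whose leading-k cumulative explained variance >= threshold.

    ``explained_fractions`` must be non-negative, non-increasing and sum to 1
    (within tolerance).
    """
    fr = np.asarray(explained_fractions, dtype=float)
    if fr.size == 0:
        raise ValueError("explained_fractions must be non-empty")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    if np.any(fr < -1e-12):
        raise ValueError("explained fractions must be non-negative")
    if np.any(np.diff(fr) > 1e-9):
        raise ValueError("explained fractions must be non-increasing")
    if abs(fr.sum() - 1.0) > 1e-6:
        raise ValueError("explained fractions must sum to 1")
    cum = np.cumsum(fr)
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    return min(k, fr.size)


def pca_residual(frame, rate: int | None = None, threshold: float = DEFAULT_THRESHOLD,
                 n_subwindows: int = DEFAULT_SUBWINDOWS) -> ResidualFrame:
    """Remove the dominant principal components of a frame; return the residual.

    The frame is reshaped into an ``n_subwindows x w`` matrix of consecutive
    equal sub-windows (``w = len(frame) // n_subwindows``; any trailing
    remainder is carried into the residual unmodified).  Columns are
    mean-centered, the top-k principal components per
    :func:`choose_num_components` are reconstructed and, together with the
    column means, subtracted from the original samples.

    Parameters
    ----------
    frame : array-like
        The frame samples.
    rate : int, optional
        Sampling rate; bookkeeping only, not used by the decomposition.
    threshold : float
        Cumulative contribution to remove, in (0, 1].
    n_subwindows : int
        Number of sub-window rows in the embedding.
    """
    x = np.asarray(frame, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("frame must be one-dimensional")
    if n_subwindows < 1:
        raise ValueError("n_subwindows must be >= 1")
    if x.size < n_subwindows:
        raise ValueError(
            f"frame of {x.size} samples is shorter than n_subwindows={n_subwindows}")
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")

    w = x.size // n_subwindows
    head = x[: n_subwindows * w].reshape(n_subwindows, w)
    tail = x[n_subwindows * w:]

    col_means = head.mean(axis=0)
    centered = head - col_means
    total_var = float(np.sum(centered**2))

    residual = np.empty_like(x)
    residual[n_subwindows * w:] = tail  # remainder passes through unmodified

    if total_var <= 1e-20 * max(1.0, float(np.sum(head**2))):
        # all-constant (zero-variance) frame: template removal leaves nothing
        residual[: n_subwindows * w] = 0.0
        return ResidualFrame(residual=residual, removed_fraction=1.0,
                             n_components_removed=0,
                             contribution_threshold=threshold)

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    fractions = var / var.sum()
    k = choose_num_components(fractions, threshold)
    recon = (u[:, :k] * s[:k]) @ vt[:k]
    residual[: n_subwindows * w] = (centered - recon).ravel()
    return ResidualFrame(residual=residual,
                         removed_fraction=float(fractions[:k].sum()),
                         n_components_removed=k,
                         contribution_threshold=threshold)
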