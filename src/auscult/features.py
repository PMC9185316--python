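"""Per-frame feature extraction: 11 statistical + 13 cepstral + 3 spectral.

The 27-dimensional vector summarizes one PCA-residual frame:

* 11 statistical features — mean, standard deviation (n-1 form), mean
  absolute deviation, median, first/third quartile (linear interpolation),
  interquartile range, skewness (adjusted Fisher-Pearson), kurtosis (Pearson,
  normal = 3), Shannon entropy of a 16-bin amplitude histogram (bits), and
  spectral entropy (periodogram entropy normalized to [0, 1]).
* 13 Mel-frequency cepstral values — coefficients 1-12 from 25 ms Hamming
  sub-windows at a 10 ms hop, 40 triangular Mel filters spanning 0..rate/2,
  orthonormal DCT-II of the log filter energies, averaged across sub-windows;
  the 13th value is the log total frame energy.
* 3 power-spectrum features — the periodogram's peak power, the frequency at
  that peak, and the peak's share of total spectral power.

Degenerate inputs follow fixed rules: a constant frame has zero entropy and
zero skewness/kurtosis, and log energies are floored at a small epsilon so a
silent frame still yields finite cepstra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import signal, stats

from .pca_residual import ResidualFrame

__all__ = [
    "FeatureVector",
    "STAT_NAMES",
    "MFCC_NAMES",
    "SPECTRUM_NAMES",
    "FEATURE_NAMES",
    "statistical_features",
    "mfcc_features",
    "power_spectrum_features",
    "feature_vector",
]

STAT_NAMES = ("mean", "std", "mean_abs_dev", "median", "q1", "q3", "iqr",
              "skewness", "kurtosis", "shannon_entropy", "spectral_entropy")
MFCC_NAMES = tuple(f"mfcc_{i}" for i in range(1, 13)) + ("log_energy",)
SPECTRUM_NAMES = ("power_max", "freq_at_max", "max_energy_fraction")
FEATURE_NAMES = STAT_NAMES + MFCC_NAMES + SPECTRUM_NAMES

N_MEL_FILTERS = 40
N_CEPSTRA = 12
PRE_EMPHASIS = 0.97
MFCC_WIN_S = 0.025
MFCC_HOP_S = 0.010
ENTROPY_BINS = 16
_LOG_EPS = 1e-10


@dataclass
class FeatureVector:
    """The named 27-entry feature vector of one frame."""

    stats: np.ndarray     # 11 values, order STAT_NAMES
    mfcc: np.ndarray      # 13 values, order MFCC_NAMES
    spectrum: np.ndarray  # 3 values, order SPECTRUM_NAMES

    def __post_init__(self) -> None:
        if len(self.stats) != 11 or len(self.mfcc) != 13 or len(self.spectrum) != 3:
            raise ValueError("feature blocks must have sizes 11/13/3")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.stats, self.mfcc, self.spectrum])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def _shannon_entropy_bits(x: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    lo, hi = float(x.min()), float(x.max())
    if hi <= lo:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def _spectral_entropy(x: np.ndarray) -> float:
    _, pxx = signal.periodogram(x)
    total = pxx.sum()
    if total <= 0:
        return 0.0
    p = pxx[pxx > 0] / total
    h = -np.sum(p * np.log2(p))
    return float(h / np.log2(pxx.size))


def statistical_features(samples) -> np.ndarray:
    """The 11 statistical features, in the order of :data:`STAT_NAMES`."""
    x = np.asarray(samples, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    std = float(x.std(ddof=1))
    if std > 0:
        skew = float(stats.skew(x, bias=False))
        kurt = float(stats.kurtosis(x, fisher=False, bias=False))
    else:
        skew = kurt = 0.0  # degenerate rule for constant frames
    return np.array([
        float(x.mean()),
        std,
        float(np.mean(np.abs(x - x.mean()))),
        float(med),
        float(q1),
        float(q3),
        float(q3 - q1),
        skew,
        kurt,
        _shannon_entropy_bits(x),
        _spectral_entropy(x),
    ])


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, n_fft: int, rate: float) -> np.ndarray:
    edges_mel = np.linspace(0.0, _hz_to_mel(rate / 2.0), n_filters + 2)
    edges_hz = _mel_to_hz(edges_mel)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    bank = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        lo, mid, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - freqs) / max(hi - mid, 1e-12)
        bank[i] = np.maximum(0.0, np.minimum(up, down))
    return bank


def mfcc_features(frame, rate: int) -> np.ndarray:
    """13 cepstral values: mean MFCC 1-12 across sub-windows + log frame energy.

    Pre-emphasis at 0.97, 25 ms Hamming analysis sub-windows at a 10 ms hop,
    power spectra through 40 triangular Mel filters (0..rate/2), log energies
    floored at epsilon, orthonormal DCT-II, coefficients 1-12 kept.
    """
    x = np.asarray(frame, dtype=np.float64)
    win = int(round(MFCC_WIN_S * rate))
    hop = max(1, int(round(MFCC_HOP_S * rate)))
    if x.size < win:
        raise ValueError(f"frame of {x.size} samples shorter than one "
                         f"{MFCC_WIN_S * 1e3:.0f} ms analysis sub-window ({win})")

    emphasized = np.concatenate([[x[0]], x[1:] - PRE_EMPHASIS * x[:-1]])
    n_fft = max(512, 1 << (win - 1).bit_length())
    bank = _mel_filterbank(N_MEL_FILTERS, n_fft, rate)
    hamming = np.hamming(win)

    n_sub = 1 + (x.size - win) // hop
    coeffs = np.zeros(N_CEPSTRA)
    for j in range(n_sub):
        seg = emphasized[j * hop: j * hop + win] * hamming
        pspec = np.abs(np.fft.rfft(seg, n=n_fft)) ** 2 / win
        mel_e = np.log(np.maximum(bank @ pspec, _LOG_EPS))
        c = sfft.dct(mel_e, type=2, norm="ortho")
        coeffs += c[1: N_CEPSTRA + 1]
    coeffs /= n_sub

    log_energy = float(np.log(max(np.sum(x**2), _LOG_EPS)))
    return np.concatenate([coeffs, [log_energy]])


def power_spectrum_features(frame, rate: int) -> np.ndarray:
    """Peak power, frequency of the peak, and the peak's share of total power."""
    x = np.asarray(frame, dtype=np.float64)
    if x.size == 0:
        raise ValueError("frame must be non-empty")
    freqs, pxx = signal.periodogram(x, fs=rate)
    total = pxx.sum()
    if total <= 0:
        return np.array([0.0, 0.0, 1.0])  # silent frame: DC-only convention
    i = int(np.argmax(pxx))
    return np.array([float(pxx[i]), float(freqs[i]), float(pxx[i] / total)])


def feature_vector(res: ResidualFrame | np.ndarray, rate: int) -> FeatureVector:
    """Assemble the 27-entry vector stats(11) || mfcc(13) || spectrum(3)."""
    samples = res.residual if isinstance(res, ResidualFrame) else np.asarray(res)
    return FeatureVector(stats=statistical_features(samples),
                         mfcc=mfcc_features(samples, rate),
                         spectrum=power_spectrum_features(samples, rate))
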