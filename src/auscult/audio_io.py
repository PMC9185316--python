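"""WAV input/output, resampling, and the heart/lung auscultation band filters.

Recordings are held as float amplitudes in WAV full-scale units, i.e. the
interval [-1, 1].  The two band filters mirror the analog front end of an
electronic stethoscope: heart sounds are low-passed at 400 Hz, lung sounds
band-passed between 100 Hz and 2000 Hz.  Both are 4th-order Butterworth
designs applied forward-backward so that transient timing (S1/S2 onsets,
crackles) is not skewed by filter group delay.
"""

from __future__ import annotations

import enum
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "SoundKind",
    "Label",
    "AudioRecording",
    "read_wav",
    "write_wav",
    "resample",
    "heart_filter",
    "lung_filter",
    "HEART_LOWPASS_HZ",
    "LUNG_BAND_HZ",
]

#: Heart-band low-pass cutoff (Hz).
HEART_LOWPASS_HZ = 400.0
#: Lung band-pass edges (Hz).
LUNG_BAND_HZ = (100.0, 2000.0)

_FILTER_ORDER = 4


class SoundKind(str, enum.Enum):
    HEART = "heart"
    LUNG = "lung"
    NOISE = "noise"


class Label(str, enum.Enum):
    NORMAL = "normal"
    ABNORMAL = "abnormal"
    UNKNOWN = "unknown"


@dataclass
class AudioRecording:
    """A mono audio signal with its sampling rate and clinical annotation.

    Parameters
    ----------
    samples : ndarray of float
        Amplitudes in WAV full-scale units; finite, nominally in [-1, 1].
    rate : int
        Sampling rate in Hz (> 0).
    sound_kind : SoundKind
        What the recording captures: heart sounds, lung sounds, or noise.
    label : Label
        Clinical class of the recording (normal / abnormal / unknown).
    id : str
        Free-text identifier, used to key frames back to their parent.
    """

    samples: np.ndarray
    rate: int
    sound_kind: SoundKind = SoundKind.HEART
    label: Label = Label.UNKNOWN
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional (mono)")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        self.sound_kind = SoundKind(self.sound_kind)
        self.label = Label(self.label)

    @property
    def duration_s(self) -> float:
        """Length of the recording in seconds."""
        return self.samples.size / self.rate

    def with_samples(self, samples: np.ndarray, rate: int | None = None) -> "AudioRecording":
        return replace(self, samples=np.asarray(samples, dtype=np.float64),
                       rate=self.rate if rate is None else rate)


def read_wav(path: str | os.PathLike,
             sound_kind: SoundKind | str = SoundKind.HEART,
             label: Label | str = Label.UNKNOWN,
             id: str | None = None) -> AudioRecording:
    """Read a PCM WAV file into an :class:`AudioRecording`.

    Integer sample formats are rescaled to [-1, 1] by their full-scale value
    (e.g. 1/32768 for 16-bit); float WAVs are taken as-is.  Multi-channel
    files are collapsed to mono by averaging the channels.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file is not a readable PCM WAV.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises ValueError on bad headers
        raise ValueError(f"not a readable PCM WAV file: {path!r} ({exc})") from exc

    data = np.atleast_1d(data)
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype.kind == "f":
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    rec_id = id if id is not None else os.path.splitext(os.path.basename(path))[0]
    return AudioRecording(samples=samples, rate=int(rate),
                          sound_kind=sound_kind, label=label, id=rec_id)


def write_wav(path: str | os.PathLike, rec: AudioRecording) -> None:
    """Write a recording as canonical 16-bit PCM WAV (clipped to [-1, 1])."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    quantized = np.clip(np.round(clipped * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(os.fspath(path), int(rec.rate), quantized)


def resample(rec: AudioRecording, target_rate: int) -> AudioRecording:
    """Resample to ``target_rate`` Hz by polyphase rational resampling."""
    if target_rate <= 0:
        raise ValueError(f"target_rate must be positive, got {target_rate}")
    if target_rate == rec.rate:
        return rec.with_samples(rec.samples.copy())
    g = math.gcd(int(target_rate), int(rec.rate))
    up, down = int(target_rate) // g, int(rec.rate) // g
    out = signal.resample_poly(rec.samples, up, down)
    return rec.with_samples(out, rate=int(target_rate))


def _sos_filtfilt(x: np.ndarray, sos: np.ndarray) -> np.ndarray:
    # forward-backward for zero phase; padlen guarded for short inputs
    padlen = min(3 * (2 * sos.shape[0] + 1), max(x.size - 1, 0))
    return signal.sosfiltfilt(sos, x, padlen=padlen)


def heart_filter(rec: AudioRecording) -> AudioRecording:
    """Apply the heart-sound band: zero-phase low-pass at 400 Hz.

    Requires ``rate`` > 800 Hz so the cutoff sits below Nyquist.
    """
    if rec.rate <= 2 * HEART_LOWPASS_HZ:
        raise ValueError(
            f"heart_filter needs rate > {2 * HEART_LOWPASS_HZ:.0f} Hz, got {rec.rate}")
    sos = signal.butter(_FILTER_ORDER, HEART_LOWPASS_HZ, btype="low",
                        fs=rec.rate, output="sos")
    return rec.with_samples(_sos_filtfilt(rec.samples, sos))


def lung_filter(rec: AudioRecording) -> AudioRecording:
    """Apply the lung-sound band: zero-phase band-pass 100-2000 Hz.

    Requires ``rate`` > 4000 Hz so the upper edge sits below Nyquist.
    """
    lo, hi = LUNG_BAND_HZ
    if rec.rate <= 2 * hi:
        raise ValueError(f"lung_filter needs rate > {2 * hi:.0f} Hz, got {rec.rate}")
    sos = signal.butter(_FILTER_ORDER, [lo, hi], btype="band",
                        fs=rec.rate, output="sos")
    return rec.with_samples(_sos_filtfilt(rec.samples, sos))
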