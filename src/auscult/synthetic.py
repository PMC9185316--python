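"""Seeded synthetic heart/lung sound and noise-mixture generator.

The generator emulates the statistical structure the classifier relies on
rather than physiologically faithful waveforms:

* **Heart sounds** are trains of cardiac cycles at 50-80 bpm.  Each cycle
  carries an S1 transient (Gaussian-windowed ~40 Hz tone) at the cycle start
  and an S2 transient (~60 Hz tone) at a fixed systolic fraction of the
  cycle.  Abnormal recordings add band-limited murmur noise bursts filling
  systole.  The periodic S1/S2 template dominates total signal energy, which
  is exactly the dominance the PCA-residual step assumes and removes.
* **Lung sounds** are amplitude-modulated broadband noise with one breath
  envelope per respiratory cycle at 12-20 breaths/min.  Abnormal recordings
  add a wheeze tone during expiration and/or brief crackle transients.
* **Noise mixtures** model the two-microphone stethoscope: a primary channel
  (clean signal plus coupled environmental noise at a prescribed SNR) and a
  reference channel carrying the noise alone.  The coupling (gain, delay,
  multiplicative frequency shift) models the different acoustic paths; a
  frequency shift degrades digital subtraction, mirroring the media-dependent
  spectral shifts seen between a stethoscope head and an open microphone.

Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .audio_io import AudioRecording, Label, SoundKind

__all__ = [
    "HeartSpec",
    "LungSpec",
    "Coupling",
    "NoiseMixture",
    "generate_heart",
    "generate_lung",
    "mix_with_noise",
    "generate_dataset",
    "NOISE_BANDS_HZ",
]

#: Band-pass shaping of the synthetic environmental noise processes (Hz).
#: Ward-construction and airport noise stand-ins use the measured bands of
#: the corresponding real recordings; "white" is broadband.
NOISE_BANDS_HZ = {"ward": (150.0, 450.0), "airport": (100.0, 600.0), "white": None}

HEART_RATE_HZ = 2000
LUNG_RATE_HZ = 8000

# S1/S2 transient parameters: tone frequency (Hz) and Gaussian width (s).
_S1_FREQ, _S1_WIDTH = 40.0, 0.060
_S2_FREQ, _S2_WIDTH = 60.0, 0.040
_SYSTOLE_FRACTION = 0.35
_PEAK_NORM = 0.95
_FLOOR_NOISE = 0.005  # relative sensor-noise floor


@dataclass(frozen=True)
class HeartSpec:
    """Parameters of one synthetic heart recording."""

    bpm: float = 60.0
    duration_s: float = 10.0
    murmur_amp: float = 0.0
    murmur_band: tuple[float, float] = (150.0, 400.0)
    rate: int = HEART_RATE_HZ
    seed: int = 0

    def validate(self) -> None:
        if not 50.0 <= self.bpm <= 80.0:
            raise ValueError(f"bpm must lie in [50, 80], got {self.bpm}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.murmur_amp < 0:
            raise ValueError("murmur_amp must be >= 0")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        lo, hi = self.murmur_band
        if not 0 < lo < hi < self.rate / 2:
            raise ValueError(f"murmur_band {self.murmur_band} invalid for rate {self.rate}")


@dataclass(frozen=True)
class LungSpec:
    """Parameters of one synthetic lung recording."""

    breaths_per_min: float = 15.0
    duration_s: float = 15.0
    wheeze_amp: float = 0.0
    wheeze_freq: float = 400.0
    crackle_rate: float = 0.0
    rate: int = LUNG_RATE_HZ
    seed: int = 0

    def validate(self) -> None:
        if not 12.0 <= self.breaths_per_min <= 20.0:
            raise ValueError(
                f"breaths_per_min must lie in [12, 20], got {self.breaths_per_min}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.wheeze_amp < 0 or self.crackle_rate < 0:
            raise ValueError("abnormality amplitudes must be >= 0")
        if not 0 < self.wheeze_freq < self.rate / 2:
            raise ValueError("wheeze_freq must lie below Nyquist")


@dataclass(frozen=True)
class Coupling:
    """Acoustic path from the noise source to the primary microphone."""

    gain: float = 1.0
    delay_s: float = 0.0
    freq_shift: float = 1.0  # multiplicative spectral shift

    @property
    def is_identity(self) -> bool:
        return self.gain == 1.0 and self.delay_s == 0.0 and self.freq_shift == 1.0


@dataclass
class NoiseMixture:
    """Two-microphone scene: primary (signal + coupled noise) and reference."""

    primary: AudioRecording
    reference: AudioRecording
    clean: AudioRecording
    snr_db: float
    coupling: Coupling

    def __post_init__(self) -> None:
        n = self.clean.samples.size
        if not (self.primary.samples.size == self.reference.samples.size == n):
            raise ValueError("primary, reference and clean must share length")
        if not (self.primary.rate == self.reference.rate == self.clean.rate):
            raise ValueError("primary, reference and clean must share rate")


def _gaussian_tone(t: np.ndarray, center: float, freq: float, width: float) -> np.ndarray:
    sigma = width / 4.0  # ~95% of the transient inside +/- width/2
    env = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return env * np.sin(2 * np.pi * freq * (t - center))


def _bandpass_noise(rng: np.random.Generator, n: int, rate: int,
                    band: tuple[float, float]) -> np.ndarray:
    x = rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.999 * rate / 2)
    sos = signal.butter(4, [lo, hi], btype="band", fs=rate, output="sos")
    return signal.sosfilt(sos, x)


def generate_heart(spec: HeartSpec) -> AudioRecording:
    """Synthesize one heart recording from its spec.

    The recording contains ``floor(bpm * duration_s / 60)`` complete cardiac
    cycles; murmur_amp > 0 marks the recording abnormal.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate))
    t = np.arange(n) / spec.rate
    x = np.zeros(n)

    cycle_s = 60.0 / spec.bpm
    n_cycles = int(np.floor(spec.bpm * spec.duration_s / 60.0))
    murmur = None
    if spec.murmur_amp > 0:
        murmur = _bandpass_noise(rng, n, spec.rate, spec.murmur_band)
        murmur /= max(np.std(murmur), 1e-12)

    for i in range(n_cycles):
        t0 = i * cycle_s
        t_s2 = t0 + _SYSTOLE_FRACTION * cycle_s
        x += _gaussian_tone(t, t0 + 2 * _S1_WIDTH, _S1_FREQ, _S1_WIDTH)
        x += 0.8 * _gaussian_tone(t, t_s2, _S2_FREQ, _S2_WIDTH)
        if murmur is not None:
            # murmur burst spanning systole (between S1 and S2)
            a, b = t0 + 3 * _S1_WIDTH, t_s2 - _S2_WIDTH
            if b > a:
                win = np.zeros(n)
                idx = (t >= a) & (t < b)
                win[idx] = np.hanning(int(idx.sum()))
                x += spec.murmur_amp * win * murmur

    x += _FLOOR_NOISE * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= _PEAK_NORM / peak
    label = Label.ABNORMAL if spec.murmur_amp > 0 else Label.NORMAL
    return AudioRecording(x, spec.rate, SoundKind.HEART, label,
                          id=f"heart-{spec.seed}")


def generate_lung(spec: LungSpec) -> AudioRecording:
    """Synthesize one lung recording from its spec.

    Breath envelopes: one raised-cosine bump per respiratory cycle for
    ``floor(breaths_per_min * duration_s / 60)`` complete cycles.  Wheeze
    (tonal, during expiration) and crackles (brief transients) mark the
    recording abnormal.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate))
    t = np.arange(n) / spec.rate

    breath_s = 60.0 / spec.breaths_per_min
    n_breaths = int(np.floor(spec.breaths_per_min * spec.duration_s / 60.0))
    envelope = np.zeros(n)
    expiration = np.zeros(n)  # weight of the expiratory half of each cycle
    for i in range(n_breaths):
        phase = (t - i * breath_s) / breath_s
        inside = (phase >= 0) & (phase < 1)
        envelope[inside] = np.maximum(envelope[inside],
                                      np.sin(np.pi * phase[inside]) ** 2)
        expi = inside & (phase >= 0.5)
        expiration[expi] = np.sin(np.pi * (phase[expi] - 0.5) / 0.5) ** 2

    breath_noise = _bandpass_noise(rng, n, spec.rate, (100.0, 1000.0))
    breath_noise /= max(np.std(breath_noise), 1e-12)
    x = envelope * breath_noise

    if spec.wheeze_amp > 0:
        x += spec.wheeze_amp * expiration * np.sin(2 * np.pi * spec.wheeze_freq * t)

    n_crackles = int(np.floor(spec.crackle_rate * spec.duration_s))
    if n_crackles > 0:
        width = 0.004  # 4 ms damped transient
        centers = rng.uniform(0.05 * spec.duration_s, 0.95 * spec.duration_s,
                              size=n_crackles)
        for c in centers:
            x += 0.8 * _gaussian_tone(t, c, 650.0, width)

    x += _FLOOR_NOISE * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= _PEAK_NORM / peak
    abnormal = spec.wheeze_amp > 0 or spec.crackle_rate > 0
    return AudioRecording(x, spec.rate, SoundKind.LUNG,
                          Label.ABNORMAL if abnormal else Label.NORMAL,
                          id=f"lung-{spec.seed}")


def _apply_coupling(noise: np.ndarray, rate: int, coupling: Coupling) -> np.ndarray:
    out = noise
    if coupling.freq_shift != 1.0:
        # time-stretch by 1/shift: spectrum scales multiplicatively by shift
        m = max(2, int(round(noise.size / coupling.freq_shift)))
        stretched = signal.resample(noise, m)
        if m >= noise.size:
            out = stretched[: noise.size]
        else:
            out = np.concatenate([stretched, np.zeros(noise.size - m)])
    if coupling.delay_s != 0.0:
        d = int(round(coupling.delay_s * rate))
        shifted = np.zeros_like(out)
        if d >= 0:
            shifted[d:] = out[: out.size - d] if d < out.size else 0.0
        else:
            shifted[:d] = out[-d:]
        out = shifted
    return coupling.gain * out


def mix_with_noise(clean: AudioRecording, noise_kind: str = "ward",
                   snr_db: float = 0.0, coupling: Coupling | None = None,
                   seed: int = 0) -> NoiseMixture:
    """Mix a clean recording with shaped environmental noise at a given SNR.

    The coupled noise reaching the primary microphone is scaled so that
    clean-to-noise power equals ``snr_db``.  The reference channel carries
    the same noise process *before* coupling; with identity coupling the
    subtraction ``primary - reference`` recovers ``clean`` exactly.
    """
    if noise_kind not in NOISE_BANDS_HZ:
        raise ValueError(f"noise_kind must be one of {sorted(NOISE_BANDS_HZ)}")
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    coupling = coupling or Coupling()
    rng = np.random.default_rng(seed)
    n, rate = clean.samples.size, clean.rate
    band = NOISE_BANDS_HZ[noise_kind]
    base = (rng.standard_normal(n) if band is None
            else _bandpass_noise(rng, n, rate, band))

    coupled = _apply_coupling(base, rate, coupling)
    p_clean = float(np.mean(clean.samples**2))
    p_coupled = float(np.mean(coupled**2))
    if p_coupled <= 0:
        raise ValueError("degenerate noise process (zero power)")
    scale = np.sqrt(p_clean / (p_coupled * 10.0 ** (snr_db / 10.0)))

    primary = clean.with_samples(clean.samples + scale * coupled)
    reference = AudioRecording(scale * base, rate, SoundKind.NOISE,
                               Label.UNKNOWN, id=f"{clean.id}-ref")
    return NoiseMixture(primary=primary, reference=reference, clean=clean,
                        snr_db=snr_db, coupling=coupling)


def generate_dataset(n_normal: int, n_abnormal: int, kind: str | SoundKind,
                     seed: int = 0, duration_s: float | None = None,
                     murmur_amp: float = 0.5, wheeze_amp: float = 0.4,
                     crackle_rate: float = 2.0) -> list[AudioRecording]:
    """Generate a labeled corpus with physiologic parameters drawn uniformly.

    Heart rates are drawn from [50, 80] bpm, respiratory rates from
    [12, 20] breaths/min.  Abnormal heart recordings carry a systolic murmur
    at ``murmur_amp``; abnormal lung recordings a wheeze and/or crackles.
    Deterministic given ``seed``.
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("counts must be >= 0")
    kind = SoundKind(kind)
    if kind is SoundKind.NOISE:
        raise ValueError("dataset kind must be heart or lung")
    rng = np.random.default_rng(seed)
    out: list[AudioRecording] = []
    for i in range(n_normal + n_abnormal):
        abnormal = i >= n_normal
        sub = int(rng.integers(0, 2**31 - 1))
        if kind is SoundKind.HEART:
            dur = 10.0 if duration_s is None else duration_s
            spec = HeartSpec(bpm=float(rng.uniform(50, 80)), duration_s=dur,
                             murmur_amp=murmur_amp if abnormal else 0.0,
                             seed=sub)
            rec = generate_heart(spec)
        else:
            dur = 15.0 if duration_s is None else duration_s
            mode = int(rng.integers(0, 3))  # wheeze / crackles / both
            spec = LungSpec(breaths_per_min=float(rng.uniform(12, 20)),
                            duration_s=dur,
                            wheeze_amp=wheeze_amp if abnormal and mode != 1 else 0.0,
                            wheeze_freq=float(rng.uniform(200, 800)),
                            crackle_rate=crackle_rate if abnormal and mode != 0 else 0.0,
                            seed=sub)
            rec = generate_lung(spec)
        rec.id = f"{kind.value}-{i:04d}"
        out.append(rec)
    return out
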