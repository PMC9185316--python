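import numpy as np
import pytest

from auscult import AudioRecording, HeartSpec, LungSpec, SoundKind, generate_heart


def make_sine(freq: float, rate: int, duration_s: float, amp: float = 1.0,
              kind: SoundKind = SoundKind.NOISE) -> AudioRecording:
    t = np.arange(int(round(duration_s * rate))) / rate
    return AudioRecording(amp * np.sin(2 * np.pi * freq * t), rate,
                          sound_kind=kind, id=f"sine{freq:g}")


@pytest.fixture(scope="session")
def heart_rec() -> AudioRecording:
    return generate_heart(HeartSpec(bpm=60, duration_s=10, seed=7))


@pytest.fixture(scope="session")
def abnormal_heart_rec() -> AudioRecording:
    return generate_heart(HeartSpec(bpm=60, duration_s=10, murmur_amp=0.5, seed=7))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
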