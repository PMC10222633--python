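import numpy as np
import pytest

from sri.audio import AudioClip
from sri.core import AuralLabel

RATE = 48000
# bin-centred tone near 5 kHz: 107 bins x 46.875 Hz, so a 1024-point
# rectangular window holds an integer number of cycles (no leakage)
TONE_HZ = 107 * 46.875


def make_noise_clip(seed: int, duration: float = 2.0, rate: int = RATE,
                    amplitude: float = 0.3) -> AudioClip:
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    return AudioClip(amplitude * rng.standard_normal(n), rate, id=f"noise{seed}")


def make_tone_clip(freq: float = TONE_HZ, duration: float = 2.0,
                   rate: int = RATE, amplitude: float = 0.5) -> AudioClip:
    t = np.arange(int(duration * rate)) / rate
    return AudioClip(amplitude * np.sin(2 * np.pi * freq * t), rate, id="tone")


@pytest.fixture(scope="session")
def noise_clip() -> AudioClip:
    return make_noise_clip(seed=12345, duration=5.0)


@pytest.fixture(scope="session")
def tone_clip() -> AudioClip:
    return make_tone_clip(duration=5.0)


@pytest.fixture(scope="session")
def minute_clip() -> AudioClip:
    """A full one-minute 48 kHz clip (band-limited noise plus a chirp bed)."""
    rng = np.random.default_rng(777)
    n = 60 * RATE
    t = np.arange(n) / RATE
    x = 0.2 * rng.standard_normal(n)
    x += 0.3 * np.sin(2 * np.pi * (3000 + 500 * np.sin(2 * np.pi * 0.5 * t)) * t)
    return AudioClip(x, RATE, id="minute", site="S01")


def make_label(**overrides) -> AuralLabel:
    base = dict(
        birds_abundance="many", species_richness="gt2",
        singing_activity_pct=60.0, traffic_type="continuous",
        traffic_intensity="low", other_sources="absent",
        recording_id="r1", site_id="S1",
    )
    base.update(overrides)
    return AuralLabel(**base)
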