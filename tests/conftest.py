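import numpy as np
import pytest

from voxsced import AudioClip, track_pitch
from voxsced.synthetic_data import VowelSpec, synth_vowel

SR = 16000


@pytest.fixture(scope="session")
def clean_vowel():
    """3 s low-perturbation, high-harmonicity sustained vowel + truth."""
    clip, truth = synth_vowel(VowelSpec(
        f0_hz=150.0, duration_s=3.0, jitter_pct=0.3, shimmer_pct=2.0,
        target_hnr_db=30.0, seed=101))
    return clip, truth


@pytest.fixture(scope="session")
def clean_vowel_pitch(clean_vowel):
    clip, _ = clean_vowel
    return track_pitch(clip)


@pytest.fixture
def sine_clip():
    def make(freq=220.0, dur=1.0, amp=1.0, sr=SR):
        t = np.arange(int(dur * sr)) / sr
        return AudioClip(amp * np.sin(2 * np.pi * freq * t), sr)
    return make
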