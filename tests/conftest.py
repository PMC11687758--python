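import numpy as np
import pytest

from nasalkit.audio_io import DualChannelRecording
from nasalkit.synth import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Three speakers, two utterances each — cheap shared material."""
    cfg = SynthConfig(seed=7, n_speakers=3, utterances_per_speaker=2,
                      nasality_levels=(0.0, 0.3, 0.7), cohort_tag="tiny")
    return generate_cohort(cfg)


@pytest.fixture()
def tone_recording():
    """One second of dual-channel tones at 44.1 kHz."""
    sr = 44_100
    t = np.arange(sr) / sr
    nose = 0.3 * np.sin(2 * np.pi * 600.0 * t)
    mouth = 0.3 * np.sin(2 * np.pi * 1500.0 * t)
    return DualChannelRecording(nose=nose, mouth=mouth, sample_rate=sr,
                                speaker_id="s1", utterance_id="u1")
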