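import numpy as np
import pytest

from pdvoice.features import VoiceRecording, detect_pitch_frames, detect_pulses
from pdvoice.synthetic import CohortSpec, VoiceSynthSpec, gen_cohort, synth_voice


@pytest.fixture(scope="session")
def sine_recording():
    fs = 22050.0
    t = np.arange(int(2 * fs)) / fs
    return VoiceRecording(samples=np.sin(2 * np.pi * 150.0 * t), rate=fs)


@pytest.fixture(scope="session")
def clean_voice():
    """Perturbation-free synthetic vowel plus its ground-truth pulses."""
    return synth_voice(VoiceSynthSpec(jitter_sigma=0.0, shimmer_sigma=0.0, seed=1))


@pytest.fixture(scope="session")
def clean_voice_track(clean_voice):
    rec, _ = clean_voice
    return detect_pitch_frames(rec)


@pytest.fixture(scope="session")
def clean_voice_pulses(clean_voice, clean_voice_track):
    rec, _ = clean_voice
    return detect_pulses(rec, clean_voice_track)


@pytest.fixture(scope="session")
def oxford_cohort():
    """Default separable 195-row, 22-feature cohort."""
    return gen_cohort(CohortSpec(layout="oxford", seed=1))
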