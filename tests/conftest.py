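"""Shared fixtures: short synthetic signals reused across test modules."""

import numpy as np
import pytest

from speechffr.fwave import (
    TARGET_RATE,
    AudioSignal,
    extract_fundamental_waveform,
    gate_silence,
    preprocess_audio,
)
from speechffr.simulate import SynthSpeechSpec, synth_speech


def tone(freq, duration=1.0, rate=TARGET_RATE, amp=1.0, phase=0.0):
    t = np.arange(int(round(duration * rate))) / rate
    return AudioSignal(amp * np.cos(2 * np.pi * freq * t + phase), rate)


@pytest.fixture(scope="session")
def short_speech():
    """10 s of synthetic voiced speech with pauses (fixed seed)."""
    return synth_speech(SynthSpeechSpec(seed=3), 10.0)


@pytest.fixture(scope="session")
def short_speech_prepped(short_speech):
    return gate_silence(preprocess_audio(short_speech))


@pytest.fixture(scope="session")
def short_fwave(short_speech):
    """Fundamental waveform extracted from the 10 s fixture."""
    return extract_fundamental_waveform(short_speech)
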