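import logging

import numpy as np
import pytest

from heartscribe.core import AudioSignal, WindowFrame
from heartscribe.pitch import PitchConfig
from heartscribe.preprocess import PreprocessConfig
from heartscribe.shift import ShiftConfig
from heartscribe.transcriber import TranscriptionConfig

# the unresolved-window warning is expected output in several scenarios
logging.getLogger("heartscribe.shift").setLevel(logging.ERROR)


@pytest.fixture
def default_config() -> TranscriptionConfig:
    return TranscriptionConfig()


@pytest.fixture
def pitch_config() -> PitchConfig:
    return PitchConfig()


@pytest.fixture
def shift_config() -> ShiftConfig:
    return ShiftConfig()


@pytest.fixture
def preprocess_config() -> PreprocessConfig:
    return PreprocessConfig()


def make_tone(freq_hz: float, sample_rate: int = 8000, duration_s: float = 10.0,
              amp: float = 0.5, phase: float = 0.0) -> AudioSignal:
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    return AudioSignal(amp * np.sin(2 * np.pi * freq_hz * t + phase), sample_rate)


def make_tone_frame(freq_hz: float, sample_rate: int = 8000,
                    window_ms: float = 250.0, amp: float = 1.0,
                    index: int = 0) -> WindowFrame:
    n = int(round(window_ms / 1000.0 * sample_rate))
    t = np.arange(n) / sample_rate
    return WindowFrame(index=index, samples=amp * np.sin(2 * np.pi * freq_hz * t),
                       duration_ms=window_ms)
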