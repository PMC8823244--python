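import numpy as np
import pytest

from usvdetect.audio_io import Waveform
from usvdetect.features import FeatureConfig, melspec
from usvdetect.model import HybridUsvModel, ModelConfig


@pytest.fixture(scope="session")
def tiny_model_config():
    """A small architecture that keeps CNN/BiLSTM tests fast."""
    return ModelConfig(
        context=25,
        bands=124,
        cnn_1d=((5, 4), (5, 1)),
        cnn_2d=((5, 4), (5, 1)),
        lstm_hidden=8,
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_model_config):
    return HybridUsvModel(tiny_model_config)


@pytest.fixture(scope="session")
def tone_waveform():
    """One second of a 50 kHz tone at 250 kHz sampling."""
    rate = 250_000
    t = np.arange(rate) / rate
    return Waveform(samples=0.1 * np.sin(2 * np.pi * 50_000 * t), rate=rate)


@pytest.fixture(scope="session")
def tone_spec(tone_waveform):
    return melspec(tone_waveform, FeatureConfig())
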