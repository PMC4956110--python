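import numpy as np
import pytest

from songscribe.annotations import Annotation, Note
from songscribe.signal_features import SpectrogramParams


@pytest.fixture(scope="session")
def params() -> SpectrogramParams:
    return SpectrogramParams()


@pytest.fixture(scope="session")
def tone_waveform():
    """One second of a pure 4 kHz tone at the default sample rate."""
    t = np.arange(32000) / 32000.0
    return np.sin(2 * np.pi * 4000.0 * t)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_annotation(spans, timeline=1000):
    return Annotation([Note(a, b, lab) for a, b, lab in spans], timeline)


@pytest.fixture(scope="session")
def small_dataset():
    """A short synthetic dataset shared by slower integration tests."""
    from songscribe.synthetic import default_config, generate_dataset

    cfg = default_config(n_classes=5, seed=7, total_minutes=0.5, p_short_gap=0.0)
    return cfg, generate_dataset(cfg)
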