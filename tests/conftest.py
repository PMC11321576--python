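import numpy as np
import pytest

from tcngru import ModelConfig, SynthConfig, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Small but structurally complete network for fast checks."""
    return ModelConfig(input_length=12, input_channels=2, num_classes=3,
                       filters=3, kernel_size=2, dilation_rates=(1, 2),
                       pool_size=2, gru_layers=2, gru_units=4,
                       dropout_rate=0.0)


@pytest.fixture(scope="session")
def small_synth():
    """Compact synthetic corpus shared across tests (6 subjects, 64-step windows)."""
    cfg = SynthConfig(num_subjects=6, windows_per_subject_per_class=4,
                      window_length=64, channels=3, seed=99)
    return cfg, generate(cfg)
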