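import numpy as np
import pytest

from hapticstim import synthetic_eeg as se
from hapticstim import trial_design as td


@pytest.fixture
def stimset():
    return td.StimulusSet()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_generator():
    """Desk-scale EEG generator used by fast tests."""
    return se.GeneratorConfig(
        n_per_group=3,
        fs=300.0,
        window_start=(0.0, 0.8),
        window_end=(-0.6, 0.2),
        trials_per_phase={"pre": 5, "intervention": 8, "post": 5},
        seed=99,
    )
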