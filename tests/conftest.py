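import numpy as np
import pytest

from backstep.synth import GaitParams, simulate_gait


@pytest.fixture(scope="session")
def tripod_dataset():
    """Zero-noise tripod gait: 6 legs, 10 s at 200 fps, 2 Hz, duty 0.5."""
    return simulate_gait(
        GaitParams(step_frequency_hz=2.0, seed=42), duration_s=10.0, fps=200.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
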