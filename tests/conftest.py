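import numpy as np
import pytest

from nldbench.synthetic import TaskConfig, generate_encoding_model, generate_session


@pytest.fixture(scope="session")
def small_session():
    """Saturating-encoding session small enough for fast unit tests."""
    return generate_session(
        TaskConfig(n_trials=80, seed=11), n_channels=24, nonlinearity="saturating"
    )


@pytest.fixture(scope="session")
def linear_session():
    """Affine-encoding, low-noise session (ridge-optimal control)."""
    model = generate_encoding_model(24, "linear", seed=7, noise_scale=0.02)
    return generate_session(
        TaskConfig(n_trials=80, seed=13), encoding_model=model
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
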