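import numpy as np
import pytest

from mpjunction import ImageFrame, SimulationConfig, simulate_study


@pytest.fixture
def faf_frame():
    """The 30° × 30°, 768 × 768 px FAF acquisition frame."""
    return ImageFrame(30.0, 768, 291.0, "FAF")


@pytest.fixture
def slo_frame():
    return ImageFrame(36.0, 1024, 291.0, "SLO")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A 3-eye default-jitter study shared across tests (seed fixed)."""
    return simulate_study(SimulationConfig(n_eyes=3, seed=7))


@pytest.fixture(scope="session")
def zero_jitter_study():
    """A 2-eye study with exact graders: the perfect-agreement limit."""
    return simulate_study(SimulationConfig(n_eyes=2, seed=7).with_jitter(0.0))
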