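import numpy as np
import pytest

from pedreg.geometry import make_camera
from pedreg.phantom import make_case


@pytest.fixture(scope="session")
def case():
    """Noise-free simulated vertebra case (no DRR rendering)."""
    return make_case(render=False)


@pytest.fixture(scope="session")
def noisy_case():
    """Same phantom with 0.5 px annotation noise."""
    return make_case(landmark_noise_px=0.5, seed=7, render=False)


@pytest.fixture(scope="session")
def small_camera():
    """64x64 detector, magnification 2 at the world origin."""
    return make_camera("ap", 1000.0, 500.0, (64, 64), 1.0, (0.0, 0.0, 0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
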