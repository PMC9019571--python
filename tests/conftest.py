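import numpy as np
import pytest

import tumorpulse as tp


@pytest.fixture(scope="session")
def fast_steps():
    """Scaled time-step hierarchy used for whole-simulation tests.

    The implicit transport solver is unconditionally stable, so a 1-min
    diffusion step and 5-min mechanics step trade accuracy (covered by the
    convergence-guard test) for runtime.
    """
    return tp.TimeStepConfig(diffusion=1.0, mechanics=5.0)


@pytest.fixture(scope="session")
def fast_config(fast_steps):
    """Default 2-D disc experiment with the reference pulsed schedule."""
    return tp.SimulationConfig(steps=fast_steps)


@pytest.fixture(scope="session")
def surrogate():
    return tp.load_network()


def pytest_configure(config):
    np.seterr(all="raise", under="ignore")
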