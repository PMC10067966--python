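import numpy as np
import pytest

from latentnav.neural import make_session
from latentnav.task import ControllerParams, TaskConfig


@pytest.fixture(scope="session")
def small_session():
    """8-neuron, 60-trial generative session with three known couplings."""
    return make_session(
        n_neurons=8, n_trials=60, seed=11,
        coupling_pairs=[(0, 1, 1.0), (2, 3, -1.0), (4, 1, 0.8)],
    )


@pytest.fixture(scope="session")
def recovery_session():
    """The parameter-recovery session: 20 neurons, 500 trials, 10 true
    couplings, generated once and shared by the encoding and decoding
    acceptance checks."""
    return make_session(n_neurons=20, n_trials=500, seed=2025,
                        n_coupling_pairs=10)


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def noiseless_ctrl():
    return ControllerParams(motor_noise_sd=0.0, sensory_noise_sd=0.0,
                            sensory_noise_sd_ang=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
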