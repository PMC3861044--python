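import numpy as np
import pytest

from baroafferent import composite, stimuli
from baroafferent.fixtures_io import nominal_model_config
from baroafferent.mechanoreceptors import VoigtChainParams


@pytest.fixture
def chain1():
    return VoigtChainParams(alpha=(0.5,), beta=(0.5,))


@pytest.fixture
def chain2():
    return VoigtChainParams(alpha=(0.5, 0.4), beta=(0.5, 2.0))


@pytest.fixture
def chain3():
    return VoigtChainParams(alpha=(0.5, 0.4, 1.0), beta=(0.5, 2.0, 10.0))


@pytest.fixture
def sinusoid_127():
    return stimuli.Sinusoid(
        stimuli.SinusoidParams(
            mean_pressure=127.0, amplitude=5.0, angular_frequency=6.44, phase=46.84
        )
    )


@pytest.fixture
def step_143():
    return stimuli.Step(
        stimuli.StepParams(p_base=115.0, p_target=143.0, onset=2.0, steepness=1.0)
    )


@pytest.fixture
def square_180():
    return stimuli.Square(
        stimuli.SquareParams(p_base=140.0, p_up=180.0, t_up=4.6, t_down=8.7)
    )


def constant_stimulus(pressure: float) -> stimuli.Ramp:
    """A constant-pressure stimulus (degenerate flat ramp)."""
    return stimuli.Ramp(
        stimuli.RampParams(p_start=pressure, p_end=pressure, t_start=0.0, t_end=1.0)
    )


@pytest.fixture
def preferred_model():
    return composite.model_from_dict(nominal_model_config("nonlinear", 2, "integrate_fire"))


@pytest.fixture
def linear_v2_model():
    return composite.model_from_dict(nominal_model_config("linear", 2, "linear"))


def make_model(wall_kind, n_voigt, neuron_kind):
    return composite.model_from_dict(nominal_model_config(wall_kind, n_voigt, neuron_kind))


ALL_CANONICAL = [
    ("linear", 1, "linear"),
    ("linear", 2, "linear"),
    ("linear", 3, "linear"),
    ("sls", 2, "linear"),
    ("nonlinear", 2, "linear"),
    ("nonlinear", 2, "integrate_fire"),
]
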