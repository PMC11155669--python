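import numpy as np
import pytest

from tcirc import ParameterSet, Scenario, endogenous_steady_state, simulate


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    """Default (published mouse calibration) parameter set."""
    return ParameterSet()


@pytest.fixture(scope="session")
def steady_state(params) -> np.ndarray:
    return endogenous_steady_state(params)


@pytest.fixture(scope="session")
def traj_20e6_f09(params):
    """Reference scenario: 20 million cells, CCR7+ fraction 0.9, 360 h."""
    return simulate(Scenario(dose=20e6, f_ccr7_ex=0.9, horizon=360.0), params)
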