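import numpy as np
import pytest

from estmap.reconcile import FilterParams
from estmap.simulate import SimConfig, simulate

#: the planted-scenario mix used by the recovery tests
SCENARIO_MIX = {"A": 3, "B": 3, "C": 2, "D": 2, "E": 10,
                "F": 2, "G": 2, "H": 4, "I": 3, "J": 2}


@pytest.fixture(scope="session")
def planted_result():
    return simulate(SimConfig(seed=1, scenario_counts=dict(SCENARIO_MIX)))


@pytest.fixture(scope="session")
def default_params():
    return FilterParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
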