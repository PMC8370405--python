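import numpy as np
import pytest

from neuroloop.cohort import CohortParams
from neuroloop.gp import GPConfig
from neuroloop.task_space import build_task_space


@pytest.fixture(scope="session")
def space():
    return build_task_space()


@pytest.fixture(scope="session")
def gp_config():
    return GPConfig()


@pytest.fixture(scope="session")
def cohort_params():
    return CohortParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
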