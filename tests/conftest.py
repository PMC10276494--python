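import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cortimuscle.montage import default_montage
from cortimuscle.paradigm import TaskParadigm


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def paradigm():
    return TaskParadigm()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
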