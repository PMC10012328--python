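import numpy as np
import pytest
from hypothesis import settings

from thetastdp import ModelConfig, NeuronParams, PlasticityParams

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def config():
    return ModelConfig()


@pytest.fixture
def neuron():
    return NeuronParams()


@pytest.fixture
def plast():
    return PlasticityParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
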