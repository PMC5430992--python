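import numpy as np
import pytest

from chaores import REGION1, REGION2, NeuronParams, SignalParams


@pytest.fixture(scope="session")
def region1() -> NeuronParams:
    return REGION1


@pytest.fixture(scope="session")
def region2() -> NeuronParams:
    return REGION2


@pytest.fixture(scope="session")
def weak_signal() -> SignalParams:
    return SignalParams(A=0.01, f0=0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
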