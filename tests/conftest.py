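import numpy as np
import pytest

from cicadasim.demography import GrowthParams
from cicadasim.predation import PredationParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def growth():
    """Default growth parameters: mean annual increment 0.15, threshold 1."""
    sigma = 0.3
    return GrowthParams(mu=np.log(0.15) - sigma**2 / 2, sigma=sigma, size_threshold=1.0)


@pytest.fixture(scope="session")
def predation_params():
    return PredationParams(p=4.0, a=1.0, h=0.01, ramp_years=1000)
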