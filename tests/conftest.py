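import numpy as np
import pytest

from splitlearn import ModelParams

# Best-fit parameter triples of the three published model variants.
SIM1 = dict(alpha=4.775, beta=96.792, lam=0.051)
SIM2 = dict(alpha=1.703, beta=1.848, lam=0.211)
SIM3 = dict(alpha=3.604, beta=5.057, lam=0.436)


@pytest.fixture
def sim1_params():
    return ModelParams(**SIM1)


@pytest.fixture
def sim2_params():
    return ModelParams(**SIM2, skip_unpredictable=True)


@pytest.fixture
def sim3_params():
    return ModelParams(**SIM3, skip_unpredictable=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
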