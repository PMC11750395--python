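import numpy as np
import pytest

from germflow.types import PhysioDomain, SeedLot, StageParams


@pytest.fixture
def domain():
    return PhysioDomain(L0=1.0, L1=2.0, dx=0.005)


@pytest.fixture
def germ_params():
    return StageParams(u=0.1, D=0.005)


@pytest.fixture
def seedlot():
    return SeedLot(N0=1.0, gamma=3.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20180923)
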