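import numpy as np
import pytest

from aoncb import MembraneParams


@pytest.fixture(scope="session")
def membrane() -> MembraneParams:
    """Canonical membrane: τ=15 ms, Ve=60 mV, Vi=−10 mV, VL=0."""
    return MembraneParams(tau=15e-3, Ve=60.0, Vi=-10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
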