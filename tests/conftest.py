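import numpy as np
import pytest

from tofpet import CrystalTimingParams


@pytest.fixture(scope="session")
def crystal20() -> CrystalTimingParams:
    """Default 20-mm LYSO-like crystal."""
    return CrystalTimingParams(L=20.0)


@pytest.fixture(scope="session")
def crystal40() -> CrystalTimingParams:
    return CrystalTimingParams(L=40.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
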