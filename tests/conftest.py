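import numpy as np
import pytest

from hybridcline.geo import GeoPoint, build_transect, default_transect
from hybridcline.simulate import simulate_cline_specimens

TRUE_M, TRUE_B = 0.002, -1.0


@pytest.fixture(scope="session")
def transect():
    return default_transect()


@pytest.fixture(scope="session")
def single_segment():
    return build_transect([GeoPoint(25.0865, -80.4473), GeoPoint(31.0405, -83.0752)])


@pytest.fixture(scope="session")
def cline_obs_large():
    """2,000 specimens from a known cline; enough for tight recovery."""
    return simulate_cline_specimens(TRUE_M, TRUE_B, 2000, (0.0, 1800.0), seed=20)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
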