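import numpy as np
import pytest

from fatracer import MCMCConfig, builtin_si_table1, generate_library


@pytest.fixture(scope="session")
def si_library():
    """Packaged SI library and its fractionation spec."""
    return builtin_si_table1()


@pytest.fixture(scope="session")
def fa_library():
    """Default synthetic FA library (raw profiles + mean/SD summary)."""
    profiles, lib = generate_library(seed=0)
    return profiles, lib


@pytest.fixture()
def fast_cfg():
    return MCMCConfig.fast(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
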