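import pytest

from hmwgs import SimConfig, default_library

#: fixed seed for every stochastic test in the suite
SEED = 20211013


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture()
def zero_noise():
    """Deterministic simulator settings: no jitter, no noise."""
    return SimConfig(within_line_rt_cv_pct=0.0, area_cv_pct=0.0, noise_sd=0.0)
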