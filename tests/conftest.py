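import numpy as np
import pytest

from vocopred import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cfg():
    return synthetic.default_config()


@pytest.fixture(scope="session")
def small_battery():
    """One calibrated battery draw with the two Operation-Span dropouts,
    shared across tests that only read it."""
    cfg = synthetic.default_config(missing_ospan_old=2)
    return synthetic.generate_battery(cfg, seed=42)
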