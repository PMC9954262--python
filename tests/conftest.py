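import numpy as np
import pytest

from vmdp300.simulate import SimConfig, simulate_subject


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One tiny simulated subject: 1 session, 4+6 blocks, 80 epochs."""
    cfg = SimConfig(
        n_sessions=1,
        calib_blocks=4,
        online_blocks=6,
        seed=7,
    )
    return simulate_subject(cfg)
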