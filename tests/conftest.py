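import numpy as np
import pytest

from envtrf import simulate as sim


@pytest.fixture(scope="session")
def small_study():
    """A small but fully structured two-condition study (4 subjects)."""
    cfg = sim.SimConfig(n_subjects=4, n_items=5, n_reps=20, snr_db=0.0, seed=7)
    return sim.simulate_averaged_study(cfg, dtype=np.float64)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
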