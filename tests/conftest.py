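import numpy as np
import pytest

from glycoblock.simulate import SimulationConfig, simulate_glycome


@pytest.fixture(scope="session")
def small_cohort():
    """A 60/60-sample cohort with the default planted effects."""
    cfg = SimulationConfig(n_control=60, n_case=60, seed=11)
    X, meta = simulate_glycome(cfg)
    return cfg, X, meta


@pytest.fixture(scope="session")
def null_cohort():
    """No group effect, no batch artifacts."""
    cfg = SimulationConfig(n_control=40, n_case=40, effect_size=0.0,
                           batch_shift=0.0, batch_scale=1.0, seed=7)
    X, meta = simulate_glycome(cfg)
    return cfg, X, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
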