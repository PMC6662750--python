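import numpy as np
import pytest

from circaphase.config import RunConfig
from circaphase.simulate import SimConfig, gen_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_config():
    """Training configuration scaled down for test runtime."""
    return RunConfig(restarts=3, max_epochs=150, rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """Five clean, fully phase-coupled FS participants (session-cached)."""
    cfg = SimConfig(n_participants=5, n_days=3, schedule_type="FS", coupling=1.0,
                    seed=21, temp_noise_sd=0.05, light_noise_sd=0.2)
    return gen_cohort(cfg)


@pytest.fixture(scope="session")
def one_participant(small_cohort):
    return small_cohort[0].participant
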