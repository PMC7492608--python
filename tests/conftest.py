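import numpy as np
import pytest

from betarebound import CohortConfig, TableGeometry, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return TableGeometry()


@pytest.fixture(scope="session")
def mini_cohort():
    """Two subjects, 50 trials: enough structure to run every stage."""
    cfg = CohortConfig(
        n_subjects=2,
        n_negative_coupling=1,
        n_trials=50,
        set_size=50,
        block_size=25,
        seed=7,
    )
    return generate_cohort(cfg)
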