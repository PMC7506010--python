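import numpy as np
import pytest

from armscore.models import build_feature_table
from armscore.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return SimConfig(n_subjects=6, reps_per_task=1, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    return build_feature_table(tiny_cohort)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
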