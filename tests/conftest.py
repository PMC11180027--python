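import numpy as np
import pytest

from neuroforage import CohortConfig, EffectProfile, MazeConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def maze_config():
    return MazeConfig()


@pytest.fixture
def small_cohort():
    """A cohort small enough for fast end-to-end tests."""
    return CohortConfig(group_sizes={"sham_vehicle": 4, "sham_minocycline": 3,
                                     "cci_vehicle": 6, "cci_minocycline": 4},
                        n_days_post=12, seed=7)


@pytest.fixture
def effects():
    return EffectProfile()
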