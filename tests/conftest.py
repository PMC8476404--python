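import numpy as np
import pytest

from pdcgrowth.synthetic import SimConfig, simulate_cohort, synthetic_reference_set


@pytest.fixture(scope="session")
def refs():
    return synthetic_reference_set()


@pytest.fixture(scope="session")
def small_cohort(refs):
    """A small but complete simulated cohort shared by read-only tests."""
    cfg = SimConfig(seed=7, n_children_per_cell=48)
    return simulate_cohort(cfg, refs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
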