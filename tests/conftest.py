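import numpy as np
import pytest

from skelconv import SimConfig, null_cohort, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced three-lineage cohort shared by the unit tests."""
    return simulate_cohort(SimConfig(seed=11, cells_per_lineage=300))


@pytest.fixture(scope="session")
def small_null(small_cohort):
    return null_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
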