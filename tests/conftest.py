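import numpy as np
import pytest

from explantkit.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def cohort55():
    """Default 55-sample cohort (with cell tables), shared across tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def cohort_nocells():
    """Default-size cohort without cell tables (faster)."""
    return generate_cohort(CohortConfig(seed=23, generate_cells=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
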