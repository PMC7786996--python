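import numpy as np
import pandas as pd
import pytest

from evtwin import CohortConfig, simulate_twin_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick cohort exercising all four probe classes."""
    return simulate_twin_cohort(CohortConfig(n_pairs=30, n_cpgs=400, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """The reference study conditions: 200 MZ pairs, 5000 CpGs, seed 1."""
    return simulate_twin_cohort(CohortConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_sheet():
    """Two twin families, four individuals, one sample each."""
    return pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "b1", "b2"],
            "individual_id": ["a1", "a2", "b1", "b2"],
            "family_id": ["A", "A", "B", "B"],
        }
    )
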