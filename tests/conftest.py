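import numpy as np
import pandas as pd
import pytest

from haplodomain import CohortDesign, simulate_cohort
from haplodomain.evaluation import carrier_cohort


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Two-age balanced cohort, 2 per cell (40 samples), 2 batches."""
    return simulate_cohort(CohortDesign(n_per_cell=2, n_batches=2, seed=7))


@pytest.fixture(scope="session")
def carriers() -> pd.DataFrame:
    """Single-age cohort with 20 samples per haplotype group."""
    return carrier_cohort(11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
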