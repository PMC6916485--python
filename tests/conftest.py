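import numpy as np
import pandas as pd
import pytest

from scar16.synthetic import GeneratorParams, generate_cohort
from scar16.cohort import cohort_frame, biochem_frame


@pytest.fixture(scope="session")
def default_cohort():
    """One deterministic 24-patient cohort with the default study conditions."""
    patients, biochem = generate_cohort(GeneratorParams(n_patients=24, seed=11))
    return patients, biochem


@pytest.fixture(scope="session")
def cohort_df(default_cohort):
    return cohort_frame(default_cohort[0])


@pytest.fixture(scope="session")
def biochem_df(default_cohort):
    return biochem_frame(default_cohort[1])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
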