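import numpy as np
import pytest

from metadep import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-subject, 15-metabolite cohort with the default planted signal."""
    return generate_cohort(CohortConfig(n_subjects=120, n_metabolites=15, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
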