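import numpy as np
import pytest

from grmcat import load_masq_ad_bank
from grmcat.synth import CohortSpec, default_paper_cohort, generate_cohort


@pytest.fixture(scope="session")
def bank():
    return load_masq_ad_bank()


@pytest.fixture(scope="session")
def small_cohort(bank):
    """400 respondents, theta ~ N(0,1), responses from the packaged bank."""
    return generate_cohort(CohortSpec(n=400, bank=bank, seed=314))


@pytest.fixture(scope="session")
def grouped_cohort(bank):
    """Two-group study-population cohort at reduced n for fast tests."""
    return generate_cohort(default_paper_cohort(n=1200, seed=271, bank=bank))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
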