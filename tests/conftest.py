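"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

from methylopace.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40 subjects x 3 waves, 40 CpGs with mixed planted classes."""
    return simulate_cohort(CohortConfig(n_subjects=40, n_cpgs=40, seed=5))


@pytest.fixture(scope="session")
def design(small_cohort):
    return small_cohort.design


@pytest.fixture
def rng():
    return np.random.default_rng(0)
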