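import numpy as np
import pytest

from mkfusion import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 28-case / 24-control cohort, shared across tests."""
    return generate_cohort(CohortSpec(), seed=11)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small cohort for fast CV protocol tests."""
    spec = CohortSpec(n_case=8, n_control=8, eeg_shape=(4, 3, 1), n_pet_rois=6)
    return generate_cohort(spec, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_psd_kernel(rng, n, rank=None):
    """Random PSD matrix via a Gram product (tests' independent construction)."""
    rank = rank or n
    A = rng.standard_normal((n, rank))
    return A @ A.T / rank
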