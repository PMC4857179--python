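import numpy as np
import pytest

from mebn import (
    CorrelationModel,
    kinship_from_pedigree,
    make_synthetic_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """30 families of the default 8-member template (n = 240)."""
    ped = make_synthetic_cohort(30)
    K = kinship_from_pedigree(ped)
    return ped, K, CorrelationModel.from_kinship(K)


@pytest.fixture(scope="session")
def full_cohort():
    """The 582-family study cohort (n = 4656)."""
    ped = make_synthetic_cohort(582)
    K = kinship_from_pedigree(ped)
    return ped, K, CorrelationModel.from_kinship(K)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
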