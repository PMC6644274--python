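import pytest

from lenspos import synthetic_cohort as sc


@pytest.fixture(scope="session")
def cohort79():
    """Default-calibration cohort at the study's sample size."""
    return sc.generate(sc.CohortParams(n=79, seed=42))


@pytest.fixture(scope="session")
def cohort5000():
    """Large cohort for checking emergent moments against calibration."""
    return sc.generate(sc.CohortParams(n=5000, seed=1))
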