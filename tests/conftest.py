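import pytest

from copdgrid import (
    DEFAULT_COEFFICIENTS,
    GRID126,
    GRID21,
    CohortSpec,
    enumerate_grid,
    generate_cohort,
)


@pytest.fixture(scope="session")
def coeffs():
    return DEFAULT_COEFFICIENTS


@pytest.fixture(scope="session")
def grid126(coeffs):
    return enumerate_grid(coeffs, GRID126)


@pytest.fixture(scope="session")
def grid21(coeffs):
    return enumerate_grid(coeffs, GRID21)


@pytest.fixture(scope="session")
def quota_cohort():
    """The reference synthetic cohort: n=106, exact quotas, seed 1."""
    return generate_cohort(CohortSpec(), seed=1)
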