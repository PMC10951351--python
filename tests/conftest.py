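import numpy as np
import pytest

from doserr import (
    LINEAR_QUADRATIC_TRUTH,
    LINEAR_TRUTH,
    DoseGroupSpec,
    ErrorConfig,
    GroupedCohort,
    build_ensemble,
    default_groups,
)


@pytest.fixture(scope="session")
def groups() -> DoseGroupSpec:
    return default_groups()


@pytest.fixture(scope="session")
def small_groups() -> DoseGroupSpec:
    """A light cohort (50 per group) for fast dose-matrix tests."""
    return DoseGroupSpec(
        group_bounds=("0-0.07", "0.08-0.19", "0.20-0.99", "1.00-2.49", "2.50+"),
        central_doses=(0.03, 0.12, 0.5, 1.5, 2.0),
        person_years=(70.0, 15.0, 10.0, 4.0, 1.0),
        n_individuals=(50, 50, 50, 50, 50),
    )


@pytest.fixture(scope="session")
def zero_error() -> ErrorConfig:
    return ErrorConfig()


@pytest.fixture(scope="session")
def berkson_heavy() -> ErrorConfig:
    """Unshared 20% / shared 50% Berkson, classical 20%/20%."""
    return ErrorConfig(
        sigma_share_berkson=0.5, sigma_unshare_berkson=0.2,
        sigma_share_class=0.2, sigma_unshare_class=0.2,
    )


@pytest.fixture(scope="session")
def seeded_cohort(groups) -> GroupedCohort:
    """A reproducible linear-quadratic cohort at zero Berkson error."""
    ens = build_ensemble(
        groups, ErrorConfig(sigma_share_class=0.2, sigma_unshare_class=0.2),
        LINEAR_QUADRATIC_TRUTH, m=1, n_cases=250, seed=2024,
    )
    return ens.cohort


@pytest.fixture(scope="session")
def hand_cohort() -> GroupedCohort:
    """Two groups, tiny counts, for hand-computed likelihood checks."""
    return GroupedCohort(cases=(2, 1), offsets=(1.0, 1.0))
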