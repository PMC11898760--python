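"""Shared fixtures.

The expensive objects — the default 200-subject healthy cohort, the
fitted microbiota-age model, and the disease arm — are session-scoped
so the unit and acceptance tests reuse one computation.
"""

import pytest

from miage.age import train_age_model
from miage.simulate import simulate_cohort


@pytest.fixture(scope="session")
def healthy_cohort_truth():
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def healthy_cohort(healthy_cohort_truth):
    return healthy_cohort_truth[0]


@pytest.fixture(scope="session")
def healthy_truth(healthy_cohort_truth):
    return healthy_cohort_truth[1]


@pytest.fixture(scope="session")
def age_results(healthy_cohort):
    return train_age_model(healthy_cohort, seed=1)


@pytest.fixture(scope="session")
def transfer_cohort():
    cohort, _ = simulate_cohort(seed=2, cohort_name="synthetic_healthy_b")
    return cohort


@pytest.fixture(scope="session")
def disease_cohort_truth():
    return simulate_cohort(n_subjects=60, arm="disease", seed=3)


@pytest.fixture(scope="session")
def disease_cohort(disease_cohort_truth):
    return disease_cohort_truth[0]


@pytest.fixture(scope="session")
def disease_relative_age(age_results, disease_cohort):
    return age_results.relative_age(disease_cohort)


@pytest.fixture(scope="session")
def small_cohort_truth():
    return simulate_cohort(n_subjects=30, samples_per_subject=4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_truth):
    return small_cohort_truth[0]
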