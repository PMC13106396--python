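import pytest

from fairprov.cohort_sim import CohortSpec, generate_cohort, stratified_split


@pytest.fixture(scope="session")
def default_cohort():
    """The main-experiment cohort: n = 1,000, injected gender bias -0.30."""
    return generate_cohort(CohortSpec(n_patients=1000, seed=42))


@pytest.fixture(scope="session")
def default_split(default_cohort):
    return stratified_split(default_cohort, 0.3, seed=42)


@pytest.fixture(scope="session")
def train_test(default_cohort, default_split):
    return (
        default_cohort.view(default_split.train_ids),
        default_cohort.view(default_split.test_ids),
    )


@pytest.fixture
def six_patient_fixture():
    """Hand fixture with EOD = +1: both female TPs flagged, no male TP flagged."""
    y_true = [1, 1, 1, 1, 0, 0]
    group = [0, 0, 1, 1, 0, 1]  # F F M M F M
    y_pred = [1, 1, 0, 0, 0, 0]
    return y_true, y_pred, group
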