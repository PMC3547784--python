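import pytest

from confcal import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def study_records():
    """One default study-shaped cohort (97 judges x 25 scenarios)."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture()
def tiny_config():
    return CohortConfig(
        n_students=6,
        n_experienced=4,
        n_scenarios=10,
        n_difficult=4,
        n_time_pressured=5,
        seed=7,
    )
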