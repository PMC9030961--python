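import pytest

from varsieve.synthetic_data import SyntheticCohortConfig, generate_cohort, table_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Packaged transcriptions of the published summary tables."""
    return table_fixtures()


@pytest.fixture(scope="session")
def small_bundle():
    """One deterministic synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticCohortConfig(n_patients=4, seed=11))
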