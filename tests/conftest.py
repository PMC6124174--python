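import pytest

from caphos import (
    apply_eligibility,
    assign_labels,
    default_cohort_spec,
    default_labdb_spec,
    generate_cohort,
    generate_labdb,
    worked_fixtures,
)


@pytest.fixture(scope="session")
def fixtures():
    return worked_fixtures()


@pytest.fixture(scope="session")
def cohort_records():
    """Default calibrated case-control cohort, seed 1."""
    return generate_cohort(default_cohort_spec(seed=1))


@pytest.fixture(scope="session")
def labeled_cohort(cohort_records):
    return assign_labels(apply_eligibility(cohort_records).eligible)


@pytest.fixture(scope="session")
def labdb():
    """Default synthetic laboratory extract, seed 7, 20k rows."""
    return generate_labdb(default_labdb_spec(seed=7, n_rows=20_000))
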