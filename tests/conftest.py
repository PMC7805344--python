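import pytest

from neocea.cohort import (
    build_fixture_cohort,
    default_cohort_spec,
    default_percentile_table,
)
from neocea.costs import exact_total_profile


@pytest.fixture(scope="session")
def spec():
    return default_cohort_spec()


@pytest.fixture(scope="session")
def cohort(spec):
    return build_fixture_cohort(spec)


@pytest.fixture(scope="session")
def table():
    return default_percentile_table()


@pytest.fixture(scope="session")
def components():
    return exact_total_profile()
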