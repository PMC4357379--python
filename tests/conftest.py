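import pytest

from umdpcr import classify_cohort, load_cohort_fixture


@pytest.fixture(scope="session")
def cohort_records():
    return load_cohort_fixture()


@pytest.fixture(scope="session")
def cohort_profiles(cohort_records):
    return classify_cohort(cohort_records)
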