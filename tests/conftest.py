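import pytest

from pvsignal import faers_io, synthetic
from pvsignal.cohort import build_cohort

TARGET_NAMES = ["niraparib", "zejula"]


@pytest.fixture(scope="session")
def fixture_corpus():
    """The deterministic ~200-report regression corpus."""
    return synthetic.regression_fixture()


@pytest.fixture(scope="session")
def fixture_records(fixture_corpus):
    return fixture_corpus.to_records()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_corpus):
    d = tmp_path_factory.mktemp("corpus")
    fixture_corpus.write(d)
    return d


@pytest.fixture(scope="session")
def fixture_demo(fixture_records):
    return faers_io.deduplicate(fixture_records["DEMO"])


@pytest.fixture(scope="session")
def fixture_cohort(fixture_demo, fixture_records):
    return build_cohort(fixture_demo, fixture_records["DRUG"], TARGET_NAMES)


@pytest.fixture(scope="session")
def fixture_case_of(fixture_demo):
    return {r.primaryid: r.caseid for r in fixture_demo}
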