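import pytest

from mc1rburden import io as io_
from mc1rburden.classify import RuleSet, classify_all
from mc1rburden.pipeline import run_paper_pipeline


@pytest.fixture(scope="session")
def records():
    return io_.load_variant_counts()


@pytest.fixture(scope="session")
def cohort():
    return io_.load_cohort_counts()


@pytest.fixture(scope="session")
def rules():
    return RuleSet()


@pytest.fixture(scope="session")
def classified(records, rules, cohort):
    return classify_all(records, rules, cohort)


@pytest.fixture(scope="session")
def assignments(classified):
    return classified[0]


@pytest.fixture(scope="session")
def summary(classified):
    return classified[1]


@pytest.fixture(scope="session")
def domain_table():
    return io_.load_domain_table()


@pytest.fixture(scope="session")
def domain_class_counts():
    return io_.load_domain_class_counts()


@pytest.fixture(scope="session")
def pipeline_result():
    return run_paper_pipeline()


@pytest.fixture(scope="session")
def by_key(records):
    return {r.key.removeprefix("p."): r for r in records}
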