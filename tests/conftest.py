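import pytest

from eq5dkit.cohort import fixture_cohort
from eq5dkit.pipeline import load_cohort, run_study, score_cohort


@pytest.fixture(scope="session")
def fixture_respondents():
    return fixture_cohort()


@pytest.fixture(scope="session")
def fixture_frame(fixture_respondents):
    return load_cohort(fixture_respondents)


@pytest.fixture(scope="session")
def scored_frame(fixture_frame):
    return score_cohort(fixture_frame)


@pytest.fixture(scope="session")
def fixture_report(fixture_frame):
    return run_study(fixture_frame)
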