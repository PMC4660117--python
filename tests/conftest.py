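import pytest

from igtkb import generate_fixture, load_paper_spec
from igtkb.pipeline import RunConfig, run_cohort
from igtkb.synthetic_ehr import printed_stats_frame


@pytest.fixture(scope="session")
def paper_cohort():
    """The deterministic cohort built from the packaged study tables."""
    return generate_fixture(load_paper_spec())


@pytest.fixture(scope="session")
def paper_result(paper_cohort):
    """Full pipeline output on the study-table cohort.

    The aggregate duplicate policy is required because one test's group
    sizes (|P| + |N| > |T|) arise from cancelled duplicate orders.
    """
    return run_cohort(paper_cohort, RunConfig(duplicate_policy="aggregate"))


@pytest.fixture(scope="session")
def printed_stats():
    """The published per-(test, feature) statistics."""
    return printed_stats_frame()
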