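import pytest

from regusnp.pipeline_report import run_pipeline
from regusnp.synthetic_data import study_fixture


@pytest.fixture(scope="session")
def fixture():
    """The packaged study fixture (built once per session)."""
    return study_fixture(seed=2014)


@pytest.fixture(scope="session")
def fixture_run(fixture):
    """(summary, hits) from the full pipeline on the packaged fixture."""
    return run_pipeline(fixture.leads, fixture.panels, fixture.tracks, fixture.eqtls)
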