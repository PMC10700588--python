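import pytest

from affectmap import pipeline, task_design


@pytest.fixture(scope="session")
def designs():
    return task_design.build_all_designs(seed=0)


@pytest.fixture(scope="session")
def fixture_cohort():
    """Small cohort spanning extreme latent profiles (see make_fixtures)."""
    return pipeline.make_fixtures(seed=7)
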