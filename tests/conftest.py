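import pytest
from hypothesis import settings

from ewsso import build_ewsso, load_default_rubrics

settings.register_profile("deterministic", derandomize=True, max_examples=100)
settings.load_profile("deterministic")
from ewsso.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def model():
    return build_ewsso()


@pytest.fixture(scope="session")
def rubrics(model):
    return load_default_rubrics(model)


@pytest.fixture(scope="session")
def small_run():
    """A fast end-to-end pipeline run shared by integration tests."""
    return run_pipeline(PipelineConfig(seed=11, n_patients=60))


@pytest.fixture(scope="session")
def full_run():
    """The study at full scale: two 1,000-patient datasets, all scores,
    all validation checks.  Computed once per session."""
    return run_pipeline(PipelineConfig(seed=42, n_patients=1000))
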