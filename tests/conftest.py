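import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from regshare.pipeline import PipelineConfig, run_pipeline
from regshare.synthetic_data import StudyParams, simulate_study

STUDY_SEED = 7


@pytest.fixture(scope="session")
def study():
    """Default synthetic study with planted truth (shared fixture)."""
    return simulate_study(StudyParams(), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    """The study written out as pipeline input files."""
    d = tmp_path_factory.mktemp("study")
    paths = study.write(d)
    return {k: str(v) for k, v in paths.items()}


@pytest.fixture(scope="session")
def pipeline_result(study_dir, tmp_path_factory):
    """One full pipeline run on the synthetic study."""
    out = tmp_path_factory.mktemp("run")
    config = PipelineConfig(**study_dir, n_trials=2000, seed=STUDY_SEED)
    return run_pipeline(config, out)
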