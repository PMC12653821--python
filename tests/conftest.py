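import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "cadpipe",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("cadpipe")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (140 + 23 + 14 participants)."""
    from cadpipe.synthetic import SyntheticCohortSpec, generate_cohort

    return generate_cohort(SyntheticCohortSpec(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(default_cohort):
    """Full pipeline run on the default cohort, shared across tests."""
    from cadpipe.pipeline import run_pipeline

    return run_pipeline(default_cohort)
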