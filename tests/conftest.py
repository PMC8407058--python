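import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def results_cohort():
    """The deterministic cohort carrying the published marginal counts."""
    from gastrus.fixture import build_results_cohort

    return build_results_cohort()
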