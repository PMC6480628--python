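import pytest
from hypothesis import HealthCheck, settings

from hrindex.risk import build_risk_model
from hrindex.simulate import GeneratorConfig, generate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """The reference synthetic cohort: 2000 subjects, seed 1, defaults."""
    return generate_cohort(GeneratorConfig(n_subjects=2000, seed=1))


@pytest.fixture(scope="session")
def default_model(default_cohort):
    """Risk model fitted to the reference synthetic cohort."""
    return build_risk_model(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """A smaller cohort for cheaper structural tests."""
    return generate_cohort(
        GeneratorConfig(n_subjects=600, seed=7, min_state_count=4)
    )
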