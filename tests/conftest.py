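import pytest
from hypothesis import HealthCheck, settings

from anbrainage.pipeline import PipelineConfig, run_study
from anbrainage.synthetic_cohort import CohortConfig

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """A desk-scale cohort: every group present, small grid, fast to render."""
    return CohortConfig(
        n_hc=24, n_acan=24, n_recan=10, n_followup=16, n_training=40,
        grid_shape=(10, 12, 10), seed=7,
    )


@pytest.fixture(scope="session")
def small_config(small_cohort_config) -> PipelineConfig:
    return PipelineConfig(cohort=small_cohort_config)


@pytest.fixture(scope="session")
def small_study(small_config):
    """One full end-to-end run on the small cohort, shared across tests."""
    return run_study(small_config)
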