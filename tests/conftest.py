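import warnings

import pytest
from hypothesis import HealthCheck, settings

from lipidprs import SimulationConfig, generate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# age clamping inside CV folds is expected and noisy
warnings.filterwarnings("ignore", message="age outside")


@pytest.fixture(scope="session")
def small_cohort():
    """60 subjects, 8 causal + 8 null markers; shared across read-only tests."""
    cfg = SimulationConfig(n_subjects=60, n_causal=8, n_null=8, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Complete dosages, no catalog weight noise: scores are exact."""
    cfg = SimulationConfig(
        n_subjects=80, n_causal=6, n_null=6, seed=23,
        missing_rate=0.0, weight_noise_sd=0.0,
    )
    return generate_cohort(cfg)
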