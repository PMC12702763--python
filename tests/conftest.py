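import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def small_cohort():
    """Strong two-predictor cohort for fast end-to-end checks."""
    from takeoverpls.simulate import SyntheticConfig, generate

    return generate(SyntheticConfig(
        n_participants=60, n_predictors=3, active_set=(0, 1),
        effect_vector=(1.5, -1.2), predictor_correlation=0.1,
        target_success_rate=0.55, seed=99,
    ))
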