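import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from frogpan import (
    CohortSpec,
    RTParams,
    UpdateRuleParams,
    build_analysis_table,
    simulate_cohort,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEED = 20231

_NOISELESS = CohortSpec(
    n_agents=5, participant_lr_sd=0.0, participant_intercept_sd=0.0
)


@pytest.fixture(scope="session")
def zero_linear_table():
    """Noise-free cohort generated by the condition-wise linear rule."""
    cohort = simulate_cohort(
        _NOISELESS, UpdateRuleParams().zero_noise(), RTParams().zero_noise(),
        seed=SEED,
    )
    return build_analysis_table(cohort)


@pytest.fixture(scope="session")
def zero_segmented_table():
    """Noise-free cohort generated by the broken-line rule."""
    cohort = simulate_cohort(
        _NOISELESS,
        UpdateRuleParams.segmented_defaults().zero_noise(),
        RTParams().zero_noise(),
        seed=SEED,
    )
    return build_analysis_table(cohort)


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default 50-agent cohort (linear mode, full noise model)."""
    return simulate_cohort(CohortSpec(n_agents=50), seed=SEED)


@pytest.fixture(scope="session")
def noisy_table(noisy_cohort):
    return build_analysis_table(noisy_cohort)


@pytest.fixture(scope="session")
def segmented_noisy_table():
    """Default 50-agent cohort generated by the segmented rule."""
    cohort = simulate_cohort(
        CohortSpec(n_agents=50),
        UpdateRuleParams.segmented_defaults(),
        seed=SEED + 1,
    )
    return build_analysis_table(cohort)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
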