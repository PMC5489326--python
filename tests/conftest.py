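import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared by pipeline-level tests."""
    from cmrdiast import CohortParams, simulate_cohort

    return simulate_cohort(CohortParams(n=200, seed=1234))


@pytest.fixture
def recovery_curve(rng):
    """One noiseless simulated curve with ground truth, at the recovery
    study's frame spacing."""
    from cmrdiast import draw_recovery_params, simulate_volume_curve
    from cmrdiast.synthetic_cohort import RECOVERY_N_FRAMES

    params = draw_recovery_params(rng)
    curve, truth = simulate_volume_curve(params, seed=7, n_frames=RECOVERY_N_FRAMES)
    return params, curve, truth
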