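import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def worked_ecology():
    """Ecology used in the hand-arithmetic worked examples."""
    from geminicoev import OvulationEcology

    return OvulationEcology(a=2.0, b=0.2, c=0.5, d=0.9, R_s=1.0)


@pytest.fixture
def four_region_ecology():
    """Ecology whose quadratic has both roots inside (0, E*), E* < 1."""
    from geminicoev import OvulationEcology

    return OvulationEcology(a=1.0, b=0.01, c=0.5, d=0.52, R_s=1.0)


@pytest.fixture
def mixed_scenario():
    """All four types present, pool small enough for exact enumeration."""
    from geminicoev import GeminoScenario

    return GeminoScenario(
        M=1.0,
        gamma_cost=0.1,
        alpha_share=0.05,
        lambda_surv=2.0,
        beta=0.2,
        delta=0.3,
        N_AQ=5,
        N_AQt=5,
        N_GQ=5,
        N_GQt=5,
    )
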