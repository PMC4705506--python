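import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from cohortcea import (  # noqa: E402
    InterventionCost,
    OutcomeSettings,
    SpecPair,
    three_state_model,
)


@pytest.fixture
def undiscounted_settings():
    """Settings that make closed-form arithmetic exact."""
    return OutcomeSettings(
        discount_rate_effects=0.0,
        discount_rate_costs=0.0,
        half_cycle_correction=False,
        horizon_cycles=10,
        perspective="societal",
    )


def make_pair(
    *,
    control_incidence=0.10,
    intervention_incidence=0.06,
    recovery=0.05,
    baseline_mortality=0.01,
    deteriorated_mortality=0.03,
    utilities=None,
    costs_healthcare=None,
    costs_societal=None,
    one_off=0.0,
    per_cycle=0.0,
):
    """A constant-transition 3-state pair used across tests."""
    utilities = utilities or {"baseline": 0.85, "deteriorated": 0.60}
    costs_healthcare = costs_healthcare or {"baseline": 500.0, "deteriorated": 3000.0}
    costs_societal = costs_societal or {"baseline": 200.0, "deteriorated": 1500.0}

    def arm(incidence):
        return three_state_model(
            incidence=incidence,
            recovery=recovery,
            baseline_mortality=baseline_mortality,
            deteriorated_mortality=deteriorated_mortality,
            utilities=utilities,
            costs_healthcare=costs_healthcare,
            costs_societal=costs_societal,
        )

    return SpecPair(
        intervention=arm(intervention_incidence),
        control=arm(control_incidence),
        intervention_cost=InterventionCost(one_off=one_off, per_cycle=per_cycle),
    )


@pytest.fixture
def simple_pair():
    return make_pair()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
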