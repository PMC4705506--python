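"""Shared generators for randomised model specifications."""

import numpy as np

from cohortcea import HealthState, ModelSpec, StateValues, TransitionSpec


def random_model_spec(rng: np.random.Generator, max_states: int = 6) -> ModelSpec:
    """A random valid spec: N states, one absorbing, row-stochastic exits.

    Exit probabilities from each alive state are a Dirichlet draw scaled to
    a total strictly below 1, so the residual self-transition is positive by
    construction.
    """
    n = int(rng.integers(2, max_states + 1))
    ids = [f"s{i}" for i in range(n - 1)] + ["dead"]
    states = [HealthState(id=sid, is_absorbing=(sid == "dead")) for sid in ids]
    transitions = []
    for sid in ids[:-1]:
        targets = [t for t in ids if t != sid]
        total_exit = float(rng.uniform(0.05, 0.95))
        weights = rng.dirichlet(np.ones(len(targets))) * total_exit
        for target, p in zip(targets, weights):
            transitions.append(
                TransitionSpec(from_state=sid, to_state=target, value=float(p))
            )
    state_values = {
        sid: StateValues(
            utility=float(rng.uniform(0.0, 1.0)),
            cost_healthcare=float(rng.uniform(0.0, 5000.0)),
            cost_societal=float(rng.uniform(0.0, 3000.0)),
        )
        for sid in ids[:-1]
    }
    state_values["dead"] = StateValues(utility=0.0)
    start = rng.dirichlet(np.ones(n - 1))
    return ModelSpec(
        states=states,
        transitions=transitions,
        state_values=state_values,
        start_distribution=[float(x) for x in start] + [0.0],
    )
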