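"""Markov cohort state-transition engine.

A model is a set of mutually exclusive health states — exactly one of them
absorbing (death) — with per-cycle transitions between them. The canonical
configuration has three states: baseline health, deteriorated health and
death, connected by four transitions (incidence of the deteriorated
condition, recovery, baseline mortality, and mortality in the deteriorated
state). The engine is N-state generic; :func:`three_state_model` builds the
canonical layout.

Transitions may be given as per-cycle probabilities or as instantaneous
per-year rates (converted with ``p = 1 - exp(-r * t)``). Baseline mortality
may be bound to a life table and looked up by the cohort's current age.
Mortality in the deteriorated state can be composed from baseline mortality
plus an excess hazard, either additively on the rate scale or as a rate
ratio — additive hazards keep composed probabilities valid and let age
dependence flow through cleanly.

Simulating a cohort multiplies the occupancy row vector by the cycle's
transition matrix, producing a :class:`CohortTrace` of state occupancy over
time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import LifeTableError, ModelValidationError, ResidualError

if TYPE_CHECKING:  # pragma: no cover
    from .paramdb import LifeTable

__all__ = [
    "HealthState",
    "TransitionSpec",
    "StateValues",
    "ModelSpec",
    "CohortTrace",
    "rate_to_prob",
    "prob_to_rate",
    "build_transition_matrix",
    "run_cohort_trace",
    "three_state_model",
]

ROW_SUM_ATOL = 1e-12
TRACE_ATOL = 1e-9


def rate_to_prob(rate: float, cycle_length: float = 1.0) -> float:
    """Convert a per-year instantaneous rate to a per-cycle probability.

    ``p = 1 - exp(-rate * cycle_length)``; strictly increasing in both
    arguments, maps rate 0 to probability 0 and rate → ∞ to probability → 1.
    """
    if rate < 0:
        raise ModelValidationError(f"rate must be >= 0, got {rate}")
    if cycle_length <= 0:
        raise ModelValidationError(f"cycle_length must be > 0, got {cycle_length}")
    return -math.expm1(-rate * cycle_length)


def prob_to_rate(prob: float, cycle_length: float = 1.0) -> float:
    """Convert a per-cycle probability to a per-year rate (inverse of
    :func:`rate_to_prob`): ``r = -ln(1 - p) / cycle_length``."""
    if not 0.0 <= prob < 1.0:
        raise ModelValidationError(f"probability must be in [0, 1), got {prob}")
    if cycle_length <= 0:
        raise ModelValidationError(f"cycle_length must be > 0, got {cycle_length}")
    return -math.log1p(-prob) / cycle_length


class HealthState(BaseModel):
    """One mutually exclusive health state."""

    model_config = ConfigDict(extra="forbid")

    id: str
    label: str = ""
    is_absorbing: bool = False


class StateValues(BaseModel):
    """Per-state annual rewards: a utility weight and two cost aggregates.

    Utilities live on the preference scale anchored at 0 (dead) and 1 (full
    health); value sets for some instruments admit states worse than dead, so
    values down to -1 are representable and the model-level ``utility_bounds``
    decide what is accepted. ``cost_societal`` carries social-care plus
    patient-borne costs on top of the healthcare-payer costs.
    """

    model_config = ConfigDict(extra="forbid")

    utility: float = Field(ge=-1.0, le=1.0)
    cost_healthcare: float = Field(default=0.0, ge=0.0)
    cost_societal: float = Field(default=0.0, ge=0.0)


ExcessMode = Literal["none", "additive_rate", "rate_ratio"]


class TransitionSpec(BaseModel):
    """One directed transition between states.

    ``value`` is a per-cycle probability (``scale="probability"``) or a
    per-year rate (``scale="rate"``). ``age_dependent=True`` ignores ``value``
    and looks the annual death probability up in a life table at the cohort's
    current age. ``excess`` composes this transition's hazard from the hazard
    of the transition ``excess_relative_to → to_state`` (default: the model's
    first state) plus/times ``value`` on the rate scale.
    """

    model_config = ConfigDict(extra="forbid")

    from_state: str
    to_state: str
    value: float = 0.0
    scale: Literal["probability", "rate"] = "probability"
    age_dependent: bool = False
    excess: ExcessMode = "none"
    excess_relative_to: Optional[str] = None

    @model_validator(mode="after")
    def _check_domain(self) -> "TransitionSpec":
        if self.from_state == self.to_state:
            raise ModelValidationError(
                f"explicit self-transition {self.from_state}->{self.to_state}: "
                "the diagonal is always the implied residual"
            )
        if self.excess != "none":
            if self.value < 0:
                raise ModelValidationError(
                    f"excess value must be >= 0, got {self.value}"
                )
            if self.excess == "additive_rate" and self.scale != "rate":
                raise ModelValidationError(
                    "additive excess mortality must be given on the rate scale"
                )
        elif not self.age_dependent:
            if self.scale == "probability" and not 0.0 <= self.value <= 1.0:
                raise ModelValidationError(
                    f"transition probability {self.from_state}->{self.to_state} "
                    f"must be in [0, 1], got {self.value}"
                )
            if self.scale == "rate" and self.value < 0:
                raise ModelValidationError(
                    f"transition rate {self.from_state}->{self.to_state} "
                    f"must be >= 0, got {self.value}"
                )
        return self


class ModelSpec(BaseModel):
    """Complete specification of one decision arm.

    States (exactly one absorbing), transitions, per-state rewards, the
    start occupancy and the cycle length in years. ``start_age`` anchors
    life-table lookups for age-dependent transitions.
    """

    model_config = ConfigDict(extra="forbid")

    states: list[HealthState]
    transitions: list[TransitionSpec]
    state_values: dict[str, StateValues]
    start_distribution: list[float]
    cycle_length: float = Field(default=1.0, gt=0)
    start_age: float = Field(default=70.0, ge=0)
    utility_bounds: tuple[float, float] = (0.0, 1.0)

    # -- structural validation ------------------------------------------------

    @model_validator(mode="after")
    def _validate_structure(self) -> "ModelSpec":
        ids = [s.id for s in self.states]
        if len(set(ids)) != len(ids):
            raise ModelValidationError(f"duplicate state ids: {ids}")
        if len(ids) < 2:
            raise ModelValidationError("a model needs at least 2 states")
        absorbing = [s.id for s in self.states if s.is_absorbing]
        if len(absorbing) != 1:
            raise ModelValidationError(
                f"exactly one absorbing state required, found {absorbing or 'none'}"
            )
        known = set(ids)
        seen_pairs = set()
        for tr in self.transitions:
            for ref in (tr.from_state, tr.to_state):
                if ref not in known:
                    raise ModelValidationError(
                        f"transition {tr.from_state}->{tr.to_state} references "
                        f"undeclared state '{ref}'"
                    )
            if tr.from_state == absorbing[0]:
                raise ModelValidationError(
                    f"no transition may leave the absorbing state '{absorbing[0]}'"
                )
            if (tr.from_state, tr.to_state) in seen_pairs:
                raise ModelValidationError(
                    f"duplicate transition {tr.from_state}->{tr.to_state}"
                )
            seen_pairs.add((tr.from_state, tr.to_state))
            if tr.excess != "none":
                base_from = tr.excess_relative_to or ids[0]
                if (base_from, tr.to_state) not in seen_pairs and not any(
                    t.from_state == base_from and t.to_state == tr.to_state
                    for t in self.transitions
                ):
                    raise ModelValidationError(
                        f"excess transition {tr.from_state}->{tr.to_state} needs a "
                        f"baseline transition {base_from}->{tr.to_state}"
                    )
        if set(self.state_values) != known:
            raise ModelValidationError(
                f"state_values keys {sorted(self.state_values)} do not match "
                f"state ids {sorted(known)}"
            )
        lo, hi = self.utility_bounds
        for sid, sv in self.state_values.items():
            if not lo <= sv.utility <= hi:
                raise ModelValidationError(
                    f"state_values.{sid}.utility = {sv.utility} outside "
                    f"configured bounds [{lo}, {hi}]"
                )
        dead = self.state_values[absorbing[0]]
        if dead.utility != 0.0 or dead.cost_healthcare != 0.0 or dead.cost_societal != 0.0:
            raise ModelValidationError(
                f"absorbing state '{absorbing[0]}' must have utility 0 and costs 0"
            )
        sd = self.start_distribution
        if len(sd) != len(ids):
            raise ModelValidationError(
                f"start_distribution has {len(sd)} entries for {len(ids)} states"
            )
        if any(x < 0 for x in sd):
            raise ModelValidationError("start_distribution entries must be >= 0")
        if abs(sum(sd) - 1.0) > TRACE_ATOL:
            raise ModelValidationError(
                f"start_distribution must sum to 1, got {sum(sd)!r}"
            )
        # constant (age-independent) rows can be residual-checked up front
        if not any(t.age_dependent for t in self.transitions):
            build_transition_matrix(self, 0, None)
        return self

    # -- helpers --------------------------------------------------------------

    @property
    def state_ids(self) -> list[str]:
        return [s.id for s in self.states]

    @property
    def absorbing_index(self) -> int:
        return next(i for i, s in enumerate(self.states) if s.is_absorbing)

    def state_index(self, state_id: str) -> int:
        try:
            return self.state_ids.index(state_id)
        except ValueError:
            raise ModelValidationError(f"unknown state id '{state_id}'") from None

    def find_transition(self, from_state: str, to_state: str) -> TransitionSpec:
        for tr in self.transitions:
            if tr.from_state == from_state and tr.to_state == to_state:
                return tr
        raise ModelValidationError(
            f"no transition {from_state}->{to_state} declared"
        )


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of a simulated cohort.

    ``occupancy`` has one row per cycle 0..T and one column per state; row 0
    is the start distribution. Rows sum to 1 and occupancy of the absorbing
    state never decreases.
    """

    occupancy: np.ndarray
    state_ids: list[str]
    absorbing_index: int
    start_age: float
    cycle_length: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def alive(self) -> np.ndarray:
        """Fraction of the cohort alive at each cycle (1 - death occupancy)."""
        mask = np.ones(len(self.state_ids))
        mask[self.absorbing_index] = 0.0
        return self.occupancy @ mask

    def validate(self) -> None:
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != len(self.state_ids):
            raise ModelValidationError("trace shape does not match state list")
        if np.any(occ < -TRACE_ATOL):
            raise ModelValidationError("negative occupancy in trace")
        row_sums = occ.sum(axis=1)
        bad = np.abs(row_sums - 1.0) > TRACE_ATOL
        if np.any(bad):
            t = int(np.argmax(bad))
            raise ModelValidationError(
                f"trace row {t} sums to {row_sums[t]!r}, expected 1"
            )
        dead = occ[:, self.absorbing_index]
        if np.any(np.diff(dead) < -TRACE_ATOL):
            raise ModelValidationError("absorbing-state occupancy decreased")

    def to_frame(self):
        """Trace as a DataFrame with a ``cycle`` column (age implied)."""
        import pandas as pd

        df = pd.DataFrame(self.occupancy, columns=self.state_ids)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        return df


# ---------------------------------------------------------------------------


def _annual_rate(
    tr: TransitionSpec,
    spec: ModelSpec,
    age: float,
    life_table: Optional["LifeTable"],
) -> float:
    """Per-year hazard of a non-excess transition at the given age."""
    if tr.age_dependent:
        if life_table is None:
            raise ModelValidationError(
                f"transition {tr.from_state}->{tr.to_state} is age-dependent "
                "but no life table was supplied"
            )
        q = life_table.annual_mortality(age)
        if q >= 1.0:
            return math.inf
        return prob_to_rate(q, 1.0)
    if tr.scale == "rate":
        return tr.value
    if tr.value >= 1.0:
        return math.inf
    return prob_to_rate(tr.value, spec.cycle_length)


def _cycle_probability(
    tr: TransitionSpec,
    spec: ModelSpec,
    age: float,
    life_table: Optional["LifeTable"],
) -> float:
    cl = spec.cycle_length
    if tr.excess != "none":
        base_from = tr.excess_relative_to or spec.state_ids[0]
        base = spec.find_transition(base_from, tr.to_state)
        r_base = _annual_rate(base, spec, age, life_table)
        if math.isinf(r_base):
            return 1.0
        if tr.excess == "additive_rate":
            r = r_base + tr.value
        else:  # rate_ratio
            r = r_base * tr.value
        return rate_to_prob(r, cl)
    if tr.age_dependent:
        r = _annual_rate(tr, spec, age, life_table)
        return 1.0 if math.isinf(r) else rate_to_prob(r, cl)
    if tr.scale == "rate":
        return rate_to_prob(tr.value, cl)
    return tr.value  # already a per-cycle probability; kept exact


def build_transition_matrix(
    spec: ModelSpec,
    cycle_index: int = 0,
    life_table: Optional["LifeTable"] = None,
) -> np.ndarray:
    """Per-cycle transition matrix for one cycle.

    Rates are converted to per-cycle probabilities, excess mortality is
    composed on the rate scale, and each diagonal entry is set to the
    residual so rows sum to 1. A negative residual (competing exits exceed
    1) raises :class:`ResidualError` naming the state and cycle — it is
    never silently renormalised. The absorbing row is the identity row.
    """
    n = len(spec.states)
    age = spec.start_age + cycle_index * spec.cycle_length
    mat = np.zeros((n, n))
    index = {s.id: i for i, s in enumerate(spec.states)}
    exits = np.zeros(n)
    for tr in spec.transitions:
        p = _cycle_probability(tr, spec, age, life_table)
        i, j = index[tr.from_state], index[tr.to_state]
        mat[i, j] = p
        exits[i] += p
    for i, state in enumerate(spec.states):
        if state.is_absorbing:
            mat[i, :] = 0.0
            mat[i, i] = 1.0
            continue
        residual = 1.0 - exits[i]
        if residual < -ROW_SUM_ATOL:
            raise ResidualError(state.id, cycle_index, residual)
        mat[i, i] = max(residual, 0.0)
    return mat


def run_cohort_trace(
    spec: ModelSpec,
    horizon_cycles: int,
    life_table: Optional["LifeTable"] = None,
) -> CohortTrace:
    """Simulate the cohort for ``horizon_cycles`` cycles.

    Row 0 is the start distribution; row t+1 = row t @ M_t where M_t is the
    cycle-t transition matrix (rebuilt per cycle only when some transition
    is age-dependent).
    """
    if horizon_cycles < 1:
        raise ModelValidationError(
            f"horizon_cycles must be >= 1, got {horizon_cycles}"
        )
    n = len(spec.states)
    occ = np.empty((horizon_cycles + 1, n))
    occ[0] = spec.start_distribution
    age_dep = any(t.age_dependent for t in spec.transitions)
    mat = None if age_dep else build_transition_matrix(spec, 0, life_table)
    for t in range(horizon_cycles):
        m_t = build_transition_matrix(spec, t, life_table) if age_dep else mat
        occ[t + 1] = occ[t] @ m_t
    trace = CohortTrace(
        occupancy=occ,
        state_ids=spec.state_ids,
        absorbing_index=spec.absorbing_index,
        start_age=spec.start_age,
        cycle_length=spec.cycle_length,
    )
    trace.validate()
    return trace


def three_state_model(
    *,
    incidence: float,
    recovery: float,
    baseline_mortality: Optional[float] = None,
    age_dependent_mortality: bool = False,
    excess_mortality_rate: Optional[float] = None,
    mortality_rate_ratio: Optional[float] = None,
    deteriorated_mortality: Optional[float] = None,
    utilities: dict[str, float],
    costs_healthcare: Optional[dict[str, float]] = None,
    costs_societal: Optional[dict[str, float]] = None,
    scale: Literal["probability", "rate"] = "probability",
    cycle_length: float = 1.0,
    start_age: float = 70.0,
    start_distribution: Optional[list[float]] = None,
    utility_bounds: tuple[float, float] = (0.0, 1.0),
) -> ModelSpec:
    """Build the canonical baseline / deteriorated / death model.

    Exactly one of ``excess_mortality_rate`` (additive per-year hazard on top
    of baseline mortality), ``mortality_rate_ratio`` (multiplicative), or
    ``deteriorated_mortality`` (a direct value on ``scale``) specifies death
    from the deteriorated state. Baseline mortality is either a constant
    value on ``scale`` or, with ``age_dependent_mortality=True``, a
    life-table lookup. ``utilities`` / cost dicts are keyed by
    ``"baseline"`` and ``"deteriorated"``.
    """
    given = [
        x is not None
        for x in (excess_mortality_rate, mortality_rate_ratio, deteriorated_mortality)
    ]
    if sum(given) != 1:
        raise ModelValidationError(
            "specify exactly one of excess_mortality_rate, "
            "mortality_rate_ratio or deteriorated_mortality"
        )
    if not age_dependent_mortality and baseline_mortality is None:
        raise ModelValidationError(
            "baseline_mortality required unless age_dependent_mortality=True"
        )
    costs_healthcare = costs_healthcare or {}
    costs_societal = costs_societal or {}
    transitions = [
        TransitionSpec(from_state="baseline", to_state="deteriorated",
                       value=incidence, scale=scale),
        TransitionSpec(from_state="deteriorated", to_state="baseline",
                       value=recovery, scale=scale),
        TransitionSpec(
            from_state="baseline", to_state="death",
            value=0.0 if age_dependent_mortality else baseline_mortality,
            scale=scale, age_dependent=age_dependent_mortality,
        ),
    ]
    if excess_mortality_rate is not None:
        transitions.append(TransitionSpec(
            from_state="deteriorated", to_state="death",
            value=excess_mortality_rate, scale="rate",
            excess="additive_rate", excess_relative_to="baseline",
        ))
    elif mortality_rate_ratio is not None:
        transitions.append(TransitionSpec(
            from_state="deteriorated", to_state="death",
            value=mortality_rate_ratio, scale="rate",
            excess="rate_ratio", excess_relative_to="baseline",
        ))
    else:
        transitions.append(TransitionSpec(
            from_state="deteriorated", to_state="death",
            value=deteriorated_mortality, scale=scale,
        ))
    state_values = {
        "baseline": StateValues(
            utility=utilities["baseline"],
            cost_healthcare=costs_healthcare.get("baseline", 0.0),
            cost_societal=costs_societal.get("baseline", 0.0),
        ),
        "deteriorated": StateValues(
            utility=utilities["deteriorated"],
            cost_healthcare=costs_healthcare.get("deteriorated", 0.0),
            cost_societal=costs_societal.get("deteriorated", 0.0),
        ),
        "death": StateValues(utility=0.0),
    }
    return ModelSpec(
        states=[
            HealthState(id="baseline", label="Baseline health"),
            HealthState(id="deteriorated", label="Deteriorated health"),
            HealthState(id="death", label="Death", is_absorbing=True),
        ],
        transitions=transitions,
        state_values=state_values,
        start_distribution=start_distribution or [1.0, 0.0, 0.0],
        cycle_length=cycle_length,
        start_age=start_age,
        utility_bounds=utility_bounds,
    )
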