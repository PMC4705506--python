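"""Valuation of cohort traces: discounted QALYs, costs and incremental summaries.

Attaches per-state utilities and costs to a :class:`~cohortcea.model.CohortTrace`,
accumulates them with discounting (optionally half-cycle corrected), and
compares two decision arms — intervention versus current care — as
incremental effects ΔE (QALYs), incremental costs ΔC, the incremental
cost-effectiveness ratio ICER = ΔC/ΔE and the incremental net monetary
benefit INMB = ΔE·λ − ΔC, where λ is the willingness to pay per QALY.

Also hosts the mapping of scores from other HRQoL instruments onto EQ-5D
utilities via declared (piecewise-)linear coefficient sets, whose residual
standard error feeds parameter uncertainty analysis.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import MappingRangeError, ModelValidationError
from .model import CohortTrace, ModelSpec, StateValues, run_cohort_trace

__all__ = [
    "StateValues",
    "OutcomeSettings",
    "InterventionCost",
    "ArmOutcome",
    "IncrementalResult",
    "SpecPair",
    "PairOutcome",
    "discount_factor",
    "accumulate_arm",
    "incremental",
    "evaluate_pair",
    "MappingAlgorithm",
    "MappedUtility",
    "map_to_eq5d",
]

logger = logging.getLogger(__name__)


class OutcomeSettings(BaseModel):
    """Analysis settings shared by both decision arms.

    Effects and costs carry separate annual discount rates (default 3%/yr
    each). ``perspective`` selects whose costs count: the healthcare payer
    only, or society (healthcare + social care + patient-borne).
    Half-cycle correction (default on) values each cycle at the average of
    its start and end occupancies, correcting the end-of-cycle bias of
    discrete transitions.
    """

    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    discount_rate_effects: float = Field(default=0.03, ge=0.0)
    discount_rate_costs: float = Field(default=0.03, ge=0.0)
    wtp_lambda: float = Field(default=30_000.0, gt=0.0, alias="lambda")
    perspective: Literal["healthcare", "societal"] = "societal"
    half_cycle_correction: bool = True
    horizon_cycles: int = Field(default=30, ge=1)
    cycle_length: float = Field(default=1.0, gt=0.0)
    currency: str = "EUR"


class InterventionCost(BaseModel):
    """Cost of implementing and delivering the intervention arm.

    ``one_off`` is charged at cycle 0 (undiscounted); ``per_cycle`` is a
    programme-level charge per cycle over the whole horizon, discounted at
    the cost rate.
    """

    model_config = ConfigDict(extra="forbid")

    one_off: float = Field(default=0.0, ge=0.0)
    per_cycle: float = Field(default=0.0, ge=0.0)

    def discounted_total(self, settings: "OutcomeSettings") -> float:
        per_cycle = sum(
            self.per_cycle
            * discount_factor(t, settings.discount_rate_costs, settings.cycle_length)
            for t in range(1, settings.horizon_cycles + 1)
        )
        return self.one_off + per_cycle


@dataclass
class ArmOutcome:
    """Discounted per-cohort-member totals for one decision arm."""

    qalys: float
    cost_healthcare: float
    cost_societal: float
    cost_total_for_perspective: float
    life_years: float


Dominance = Literal[
    "intervention_dominant",
    "comparator_dominant",
    "trade_off_ne_quadrant",
    "trade_off_sw_quadrant",
    "equivalent",
]


@dataclass
class IncrementalResult:
    """Incremental comparison of intervention versus current care.

    ``icer`` is reported only in the trade-off quadrants of the
    cost-effectiveness plane (ΔE and ΔC of equal sign, ΔE ≠ 0); under
    dominance it is ``None``.
    """

    delta_e: float
    delta_c: float
    inmb: float
    icer: Optional[float]
    dominance: Dominance
    wtp_lambda: float


@dataclass
class SpecPair:
    """The two decision arms plus the intervention's delivery cost."""

    intervention: ModelSpec
    control: ModelSpec
    intervention_cost: InterventionCost = field(default_factory=InterventionCost)

    def copy(self) -> "SpecPair":
        return copy.deepcopy(self)


@dataclass
class PairOutcome:
    intervention: ArmOutcome
    control: ArmOutcome
    incremental: IncrementalResult
    intervention_trace: CohortTrace
    control_trace: CohortTrace


def discount_factor(
    cycle_index: int, annual_rate: float, cycle_length: float = 1.0
) -> float:
    """Present-value factor ``(1 + rate)^(-cycle_index * cycle_length)``."""
    if annual_rate < 0:
        raise ModelValidationError(f"discount rate must be >= 0, got {annual_rate}")
    if cycle_index == 0 or annual_rate == 0.0:
        return 1.0
    return (1.0 + annual_rate) ** (-cycle_index * cycle_length)


def _discount_vector(rate: float, horizon: int, cycle_length: float) -> np.ndarray:
    return np.array(
        [discount_factor(t, rate, cycle_length) for t in range(1, horizon + 1)]
    )


def accumulate_arm(
    trace: CohortTrace,
    values: dict[str, StateValues],
    settings: OutcomeSettings,
) -> ArmOutcome:
    """Accumulate discounted QALYs, costs and life years over a trace.

    Per cycle t ≥ 1 the cohort accrues ``occupancy · reward_vector ·
    cycle_length`` discounted to present value; with half-cycle correction
    the occupancy is the mean of rows t−1 and t. QALYs use the per-state
    utility weights (one QALY = one year in full health); the two cost
    streams use their own discount rate; life years use the alive fraction
    and the effects rate (a diagnostic: with all utilities 1 and the same
    discounting, QALYs equal life years).
    """
    if set(values) != set(trace.state_ids):
        raise ModelValidationError(
            f"state values keys {sorted(values)} do not match trace states "
            f"{sorted(trace.state_ids)}"
        )
    horizon = trace.n_cycles
    if horizon != settings.horizon_cycles:
        raise ModelValidationError(
            f"trace has {horizon} cycles but settings.horizon_cycles = "
            f"{settings.horizon_cycles}"
        )
    if trace.cycle_length != settings.cycle_length:
        raise ModelValidationError(
            f"trace cycle_length {trace.cycle_length} != settings.cycle_length "
            f"{settings.cycle_length}"
        )
    cl = trace.cycle_length
    u = np.array([values[s].utility for s in trace.state_ids])
    ch = np.array([values[s].cost_healthcare for s in trace.state_ids])
    cs = np.array([values[s].cost_societal for s in trace.state_ids])
    alive = np.ones(len(trace.state_ids))
    alive[trace.absorbing_index] = 0.0

    occ = trace.occupancy
    if settings.half_cycle_correction:
        occ_eff = 0.5 * (occ[:-1] + occ[1:])
    else:
        occ_eff = occ[1:]

    df_e = _discount_vector(settings.discount_rate_effects, horizon, cl)
    df_c = _discount_vector(settings.discount_rate_costs, horizon, cl)

    qalys = float(df_e @ (occ_eff @ u)) * cl
    life_years = float(df_e @ (occ_eff @ alive)) * cl
    cost_hc = float(df_c @ (occ_eff @ ch)) * cl
    cost_soc = float(df_c @ (occ_eff @ cs)) * cl
    total = cost_hc if settings.perspective == "healthcare" else cost_hc + cost_soc
    return ArmOutcome(
        qalys=qalys,
        cost_healthcare=cost_hc,
        cost_societal=cost_soc,
        cost_total_for_perspective=total,
        life_years=life_years,
    )


def incremental(
    intervention: ArmOutcome,
    control: ArmOutcome,
    settings: OutcomeSettings,
    intervention_cost: Optional[InterventionCost] = None,
) -> IncrementalResult:
    """ΔE, ΔC, ICER, INMB and dominance classification.

    The discounted intervention delivery cost is added to the intervention
    arm's costs before differencing. INMB = ΔE·λ − ΔC always; the ICER is
    only meaningful when the point lies in the NE (more effect, more cost)
    or SW (less effect, less cost) quadrant of the CE plane.
    """
    delta_e = intervention.qalys - control.qalys
    delivery = (
        intervention_cost.discounted_total(settings) if intervention_cost else 0.0
    )
    delta_c = (
        intervention.cost_total_for_perspective + delivery
        - control.cost_total_for_perspective
    )
    inmb = delta_e * settings.wtp_lambda - delta_c

    icer: Optional[float] = None
    if delta_e == 0.0 and delta_c == 0.0:
        dominance: Dominance = "equivalent"
    elif delta_e >= 0.0 and delta_c <= 0.0:
        dominance = "intervention_dominant"
    elif delta_e <= 0.0 and delta_c >= 0.0:
        dominance = "comparator_dominant"
    elif delta_e > 0.0:  # delta_c > 0
        dominance = "trade_off_ne_quadrant"
        icer = delta_c / delta_e
    else:  # delta_e < 0, delta_c < 0
        dominance = "trade_off_sw_quadrant"
        icer = delta_c / delta_e
    return IncrementalResult(
        delta_e=delta_e,
        delta_c=delta_c,
        inmb=inmb,
        icer=icer,
        dominance=dominance,
        wtp_lambda=settings.wtp_lambda,
    )


def evaluate_pair(
    pair: SpecPair,
    settings: OutcomeSettings,
    life_table=None,
) -> PairOutcome:
    """Run both arms under identical settings and compare them."""
    for label, spec in (("intervention", pair.intervention), ("control", pair.control)):
        if spec.cycle_length != settings.cycle_length:
            raise ModelValidationError(
                f"{label} arm cycle_length {spec.cycle_length} != settings "
                f"cycle_length {settings.cycle_length}"
            )
    tr_int = run_cohort_trace(pair.intervention, settings.horizon_cycles, life_table)
    tr_ctl = run_cohort_trace(pair.control, settings.horizon_cycles, life_table)
    out_int = accumulate_arm(tr_int, pair.intervention.state_values, settings)
    out_ctl = accumulate_arm(tr_ctl, pair.control.state_values, settings)
    inc = incremental(out_int, out_ctl, settings, pair.intervention_cost)
    return PairOutcome(
        intervention=out_int,
        control=out_ctl,
        incremental=inc,
        intervention_trace=tr_int,
        control_trace=tr_ctl,
    )


# -- HRQoL instrument mapping ------------------------------------------------


class MappingSegment(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lower: float
    upper: float
    intercept: float
    slope: float

    @model_validator(mode="after")
    def _ordered(self) -> "MappingSegment":
        if self.upper <= self.lower:
            raise ModelValidationError(
                f"segment bounds out of order: [{self.lower}, {self.upper}]"
            )
        return self


class MappingAlgorithm(BaseModel):
    """A published cross-walk from another HRQoL instrument onto EQ-5D.

    Piecewise-linear: each segment covers ``[lower, upper)`` of the source
    score (the last segment is closed above) and predicts
    ``intercept + slope * score``. ``residual_se`` is the algorithm's
    residual standard error — the extra uncertainty the conversion adds,
    which PSA can attach to the mapped utility.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    source_instrument: str = ""
    segments: list[MappingSegment]
    residual_se: float = Field(default=0.0, ge=0.0)
    utility_bounds: tuple[float, float] = (0.0, 1.0)

    @classmethod
    def linear(
        cls,
        name: str,
        intercept: float,
        slope: float,
        input_range: tuple[float, float],
        residual_se: float = 0.0,
        **kw,
    ) -> "MappingAlgorithm":
        lo, hi = input_range
        return cls(
            name=name,
            segments=[MappingSegment(lower=lo, upper=hi, intercept=intercept, slope=slope)],
            residual_se=residual_se,
            **kw,
        )

    @model_validator(mode="after")
    def _contiguous(self) -> "MappingAlgorithm":
        if not self.segments:
            raise ModelValidationError("mapping algorithm needs >= 1 segment")
        segs = sorted(self.segments, key=lambda s: s.lower)
        for a, b in zip(segs, segs[1:]):
            if b.lower != a.upper:
                raise ModelValidationError(
                    f"mapping segments not contiguous at {a.upper} / {b.lower}"
                )
        self.segments = segs
        return self

    @property
    def input_range(self) -> tuple[float, float]:
        return self.segments[0].lower, self.segments[-1].upper


@dataclass
class MappedUtility:
    utility: float
    standard_error: float
    clamped: bool = False


def map_to_eq5d(
    score: float,
    algorithm: MappingAlgorithm,
    allow_extrapolation: bool = False,
) -> MappedUtility:
    """Convert a source-instrument score to an EQ-5D utility.

    Scores outside the algorithm's declared input range are refused unless
    ``allow_extrapolation=True`` (the nearest segment is then extended).
    Predictions outside the configured utility bounds are clamped to the
    boundary and the clamp is logged and flagged on the result.
    """
    lo, hi = algorithm.input_range
    if not lo <= score <= hi:
        if not allow_extrapolation:
            raise MappingRangeError(
                f"score {score} outside declared input range [{lo}, {hi}] of "
                f"mapping '{algorithm.name}' (pass allow_extrapolation=True "
                "to override)"
            )
        segment = algorithm.segments[0] if score < lo else algorithm.segments[-1]
    else:
        segment = algorithm.segments[-1]
        for seg in algorithm.segments:
            if seg.lower <= score < seg.upper:
                segment = seg
                break
    predicted = segment.intercept + segment.slope * score
    blo, bhi = algorithm.utility_bounds
    clamped = not blo <= predicted <= bhi
    if clamped:
        clipped = min(max(predicted, blo), bhi)
        logger.warning(
            "mapping '%s': predicted utility %.6g clamped to %.6g "
            "(bounds [%g, %g])", algorithm.name, predicted, clipped, blo, bhi,
        )
        predicted = clipped
    return MappedUtility(
        utility=predicted, standard_error=algorithm.residual_se, clamped=clamped
    )
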