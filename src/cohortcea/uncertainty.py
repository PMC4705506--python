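"""Parameter uncertainty: probabilistic sensitivity analysis and scenarios.

Each uncertain input is described by a :class:`ParameterDistribution` — a
target path into the spec pair plus a distribution family, parameterised
either naturally or by (mean, standard error) through method-of-moments
fits. PSA samples every parameter independently per draw, rebuilds both
arms, and records (ΔE, ΔC, INMB); draws producing invalid models (e.g.
competing exits exceeding 1) are rejected and re-drawn, with an abort once
the rejection rate exceeds a cap. Summaries include the cost-effectiveness
acceptability curve (CEAC) — the probability the intervention is
cost-effective as a function of the willingness-to-pay λ.

Deterministic companions: consecutive scenario re-evaluation
(:func:`run_scenarios`) and one-way tornado analysis
(:func:`one_way_tornado`).

Parameter paths
---------------
``<arm>.transition.<from>.<to>`` — a transition's value (``<arm>`` is
``intervention``, ``control`` or ``both``); ``<arm>.utility.<state>``;
``<arm>.cost_healthcare.<state>``; ``<arm>.cost_societal.<state>``;
``intervention_cost.one_off`` / ``intervention_cost.per_cycle``. Scenario
overrides may additionally touch ``settings.<field>``.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .errors import DistributionError, ModelValidationError, PathError, PSAError
from .model import ModelSpec
from .outcomes import OutcomeSettings, PairOutcome, SpecPair, evaluate_pair

__all__ = [
    "ParameterDistribution",
    "PSAResult",
    "ScenarioSpec",
    "fit_distribution_from_moments",
    "run_psa",
    "ceac",
    "run_scenarios",
    "one_way_tornado",
    "resolve_parameter",
    "assign_parameter",
    "target_domain",
]

logger = logging.getLogger(__name__)

Family = Literal["beta", "gamma", "lognormal", "normal", "fixed"]

DEFAULT_LAMBDA_GRID = tuple(float(x) for x in range(0, 101_000, 5_000))


def fit_distribution_from_moments(
    family: Family, mean: float, standard_error: float
) -> dict[str, float]:
    """Method-of-moments natural parameters reproducing (mean, SE).

    beta: ``k = μ(1−μ)/σ² − 1``, ``α = μk``, ``β = (1−μ)k`` (requires
    ``σ² < μ(1−μ)``); gamma: ``shape = μ²/σ²``, ``scale = σ²/μ``;
    lognormal via log-moment matching. ``fixed`` ignores the SE.
    """
    if family == "fixed":
        return {"value": mean}
    if standard_error <= 0:
        raise DistributionError(
            f"standard error must be > 0 for family '{family}', got {standard_error}"
        )
    var = standard_error**2
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise DistributionError(f"beta mean must be in (0, 1), got {mean}")
        if var >= mean * (1.0 - mean):
            raise DistributionError(
                f"infeasible beta variance: σ²={var:.6g} >= μ(1−μ)="
                f"{mean * (1 - mean):.6g}"
            )
        k = mean * (1.0 - mean) / var - 1.0
        return {"alpha": mean * k, "beta": (1.0 - mean) * k}
    if family == "gamma":
        if mean <= 0:
            raise DistributionError(f"gamma mean must be > 0, got {mean}")
        return {"shape": mean**2 / var, "scale": var / mean}
    if family == "lognormal":
        if mean <= 0:
            raise DistributionError(f"lognormal mean must be > 0, got {mean}")
        sigma2 = math.log1p(var / mean**2)
        return {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)}
    if family == "normal":
        return {"loc": mean, "scale": standard_error}
    raise DistributionError(f"unknown family '{family}'")


class ParameterDistribution(BaseModel):
    """Uncertainty description for one model input.

    Give either natural ``params`` (``alpha``/``beta``, ``shape``/``scale``,
    ``mu``/``sigma``, ``loc``/``scale``, or ``value`` for fixed) or a
    (``mean``, ``se``) pair fitted by method of moments. Optional
    ``truncation`` bounds are enforced by rejection sampling.
    """

    model_config = ConfigDict(extra="forbid")

    target: str
    family: Family
    mean: Optional[float] = None
    se: Optional[float] = Field(default=None, gt=0.0)
    params: Optional[dict[str, float]] = None
    truncation: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _parameterised(self) -> "ParameterDistribution":
        if self.params is None:
            if self.family == "fixed":
                if self.mean is None:
                    raise DistributionError(
                        f"fixed distribution for '{self.target}' needs mean or params"
                    )
            elif self.mean is None or self.se is None:
                raise DistributionError(
                    f"distribution for '{self.target}' needs params or (mean, se)"
                )
            self.params = fit_distribution_from_moments(
                self.family, self.mean, self.se if self.se is not None else 1.0
            )
        else:
            required = {
                "beta": {"alpha", "beta"},
                "gamma": {"shape", "scale"},
                "lognormal": {"mu", "sigma"},
                "normal": {"loc", "scale"},
                "fixed": {"value"},
            }[self.family]
            if set(self.params) != required:
                raise DistributionError(
                    f"family '{self.family}' needs params {sorted(required)}, "
                    f"got {sorted(self.params)}"
                )
        if self.truncation is not None and self.truncation[0] >= self.truncation[1]:
            raise DistributionError(
                f"empty truncation interval {self.truncation} for '{self.target}'"
            )
        return self

    # -- sampling / quantiles -------------------------------------------------

    def _frozen(self):
        p = self.params
        if self.family == "beta":
            return stats.beta(p["alpha"], p["beta"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=math.exp(p["mu"]))
        if self.family == "normal":
            return stats.norm(loc=p["loc"], scale=p["scale"])
        raise DistributionError(f"no continuous form for family '{self.family}'")

    def _draw_one(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "fixed":
            return p["value"]
        if self.family == "beta":
            return float(rng.beta(p["alpha"], p["beta"]))
        if self.family == "gamma":
            return float(rng.gamma(p["shape"], p["scale"]))
        if self.family == "lognormal":
            return float(rng.lognormal(p["mu"], p["sigma"]))
        if self.family == "normal":
            return float(rng.normal(p["loc"], p["scale"]))
        raise DistributionError(f"cannot sample family '{self.family}'")

    def sample(self, rng: np.random.Generator) -> float:
        """One draw; truncation enforced by rejection (never clamped)."""
        for _ in range(1000):
            x = self._draw_one(rng)
            if self.truncation is None or self.truncation[0] <= x <= self.truncation[1]:
                return x
        raise DistributionError(
            f"truncation {self.truncation} on '{self.target}' rejected 1000 "
            "consecutive draws"
        )

    def ppf(self, q: float) -> float:
        if self.family == "fixed":
            return self.params["value"]
        x = float(self._frozen().ppf(q))
        if self.truncation is not None:
            x = min(max(x, self.truncation[0]), self.truncation[1])
        return x


# -- parameter paths ---------------------------------------------------------

_ARM_NAMES = ("intervention", "control", "both")
_VALUE_KINDS = ("utility", "cost_healthcare", "cost_societal")


def _parse(path: str):
    parts = path.split(".")
    if parts[0] == "intervention_cost":
        if len(parts) != 2 or parts[1] not in ("one_off", "per_cycle"):
            raise PathError(
                f"'{path}': intervention_cost paths are "
                "'intervention_cost.one_off' or 'intervention_cost.per_cycle'"
            )
        return ("intervention_cost", parts[1])
    if parts[0] not in _ARM_NAMES:
        raise PathError(
            f"'{path}': must start with one of {_ARM_NAMES} or 'intervention_cost'"
        )
    if len(parts) >= 2 and parts[1] == "transition":
        if len(parts) != 4:
            raise PathError(f"'{path}': transition paths are '<arm>.transition.<from>.<to>'")
        return ("transition", parts[0], parts[2], parts[3])
    if len(parts) == 3 and parts[1] in _VALUE_KINDS:
        return ("state_value", parts[0], parts[1], parts[2])
    raise PathError(
        f"'{path}': expected '<arm>.transition.<from>.<to>', "
        f"'<arm>.<utility|cost_healthcare|cost_societal>.<state>' "
        "or 'intervention_cost.<one_off|per_cycle>'"
    )


def _arm_specs(pair: SpecPair, arm: str) -> list[ModelSpec]:
    if arm == "intervention":
        return [pair.intervention]
    if arm == "control":
        return [pair.control]
    return [pair.intervention, pair.control]


def resolve_parameter(pair: SpecPair, path: str) -> float:
    """Current value at ``path`` (for ``both``, the control arm's value)."""
    kind = _parse(path)
    if kind[0] == "intervention_cost":
        return getattr(pair.intervention_cost, kind[1])
    spec = _arm_specs(pair, kind[1])[-1]
    try:
        if kind[0] == "transition":
            return spec.find_transition(kind[2], kind[3]).value
        if kind[3] not in spec.state_values:
            raise PathError(f"'{path}': unknown state '{kind[3]}'")
        return getattr(spec.state_values[kind[3]], kind[2])
    except ModelValidationError as exc:
        raise PathError(f"'{path}': {exc}") from None


def target_domain(pair: SpecPair, path: str) -> tuple[float, float]:
    """Valid (lo, hi) interval for values assigned at ``path``."""
    kind = _parse(path)
    if kind[0] == "intervention_cost":
        return (0.0, math.inf)
    spec = _arm_specs(pair, kind[1])[-1]
    if kind[0] == "transition":
        try:
            tr = spec.find_transition(kind[2], kind[3])
        except ModelValidationError as exc:
            raise PathError(f"'{path}': {exc}") from None
        if tr.scale == "probability" and tr.excess == "none":
            return (0.0, 1.0)
        return (0.0, math.inf)
    if kind[3] not in spec.state_values:
        raise PathError(f"'{path}': unknown state '{kind[3]}'")
    if kind[2] == "utility":
        return spec.utility_bounds
    return (0.0, math.inf)


def assign_parameter(pair: SpecPair, path: str, value: float) -> None:
    """Write ``value`` at ``path``, enforcing the target's domain."""
    lo, hi = target_domain(pair, path)
    if not lo <= value <= hi:
        raise ModelValidationError(
            f"value {value:.6g} for '{path}' outside valid domain [{lo:g}, {hi:g}]"
        )
    kind = _parse(path)
    if kind[0] == "intervention_cost":
        setattr(pair.intervention_cost, kind[1], value)
        return
    for spec in _arm_specs(pair, kind[1]):
        if kind[0] == "transition":
            spec.find_transition(kind[2], kind[3]).value = value
        else:
            setattr(spec.state_values[kind[3]], kind[2], value)


def _check_family_compatibility(pair: SpecPair, dist: ParameterDistribution) -> None:
    lo, hi = target_domain(pair, dist.target)
    if dist.family == "beta" and not (lo >= 0.0 and hi <= 1.0):
        raise DistributionError(
            f"beta distribution on '{dist.target}' requires a [0, 1] target "
            f"(domain is [{lo:g}, {hi:g}]); use gamma or lognormal"
        )
    if dist.family in ("gamma", "lognormal") and lo < 0.0:
        raise DistributionError(
            f"{dist.family} distribution on '{dist.target}' requires a "
            "non-negative target"
        )
    if dist.mean is not None and not lo <= dist.mean <= hi:
        raise DistributionError(
            f"mean {dist.mean:.6g} of '{dist.target}' outside the target's "
            f"domain [{lo:g}, {hi:g}]"
        )


# -- probabilistic sensitivity analysis --------------------------------------


@dataclass
class PSAResult:
    """Per-draw PSA table and its provenance.

    ``draws`` holds one row per accepted draw: the sampled value of every
    parameter (columns named by target path) followed by ``delta_e``,
    ``delta_c`` and ``inmb``.
    """

    draws: pd.DataFrame
    n_draws: int
    seed: int
    wtp_lambda: float
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    n_rejected: int = 0


def run_psa(
    pair: SpecPair,
    distributions: Sequence[ParameterDistribution],
    n_draws: int,
    seed: int,
    settings: OutcomeSettings,
    life_table=None,
    rejection_cap: float = 0.05,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through both arms.

    Per draw, every distribution is sampled independently (in declared
    order, from a single generator seeded with ``seed`` — the order is part
    of the reproducibility contract), the sampled values are written into a
    copy of the spec pair, and the pair is re-evaluated. Draws that produce
    an invalid model are rejected and re-drawn; if the overall rejection
    rate exceeds ``rejection_cap`` the analysis aborts, naming the
    distributions implicated.
    """
    if n_draws < 1:
        raise PSAError(f"n_draws must be >= 1, got {n_draws}")
    for dist in distributions:
        resolve_parameter(pair, dist.target)  # raises PathError if dangling
        _check_family_compatibility(pair, dist)
    rng = np.random.default_rng(seed)
    targets = [d.target for d in distributions]
    rows: list[list[float]] = []
    rejected = 0
    offenders: Counter[str] = Counter()
    max_rejections = max(50, int(math.ceil(rejection_cap * n_draws)) + 50)
    while len(rows) < n_draws:
        sampled = [d.sample(rng) for d in distributions]
        try:
            candidate = pair.copy()
            for dist, value in zip(distributions, sampled):
                try:
                    assign_parameter(candidate, dist.target, value)
                except ModelValidationError:
                    offenders[dist.target] += 1
                    raise
            outcome = evaluate_pair(candidate, settings, life_table)
        except ModelValidationError as exc:
            rejected += 1
            logger.debug("PSA draw rejected: %s", exc)
            if rejected > max_rejections and rejected / (rejected + len(rows)) > rejection_cap:
                named = ", ".join(t for t, _ in offenders.most_common(3)) or "model structure"
                raise PSAError(
                    f"PSA aborted: {rejected} rejected draws against "
                    f"{len(rows)} accepted (cap {rejection_cap:.0%}); "
                    f"implicated distributions: {named}; last error: {exc}"
                ) from exc
            continue
        inc = outcome.incremental
        rows.append(sampled + [inc.delta_e, inc.delta_c, inc.inmb])
    if rejected:
        logger.info("PSA: %d draws rejected and re-drawn", rejected)
    rate = rejected / (rejected + n_draws)
    if rate > rejection_cap:
        named = ", ".join(t for t, _ in offenders.most_common(3)) or "model structure"
        raise PSAError(
            f"PSA rejection rate {rate:.1%} exceeds cap {rejection_cap:.0%}; "
            f"implicated distributions: {named}"
        )
    draws = pd.DataFrame(rows, columns=targets + ["delta_e", "delta_c", "inmb"])
    return PSAResult(
        draws=draws,
        n_draws=n_draws,
        seed=seed,
        wtp_lambda=settings.wtp_lambda,
        lambda_grid=tuple(lambda_grid),
        n_rejected=rejected,
    )


def ceac(result: PSAResult, lambda_grid: Optional[Sequence[float]] = None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each λ the fraction of draws with ΔE·λ − ΔC > 0 (ties count as not
    cost-effective). As λ → 0 this tends to the fraction of cost-saving
    draws; as λ → ∞ to the fraction of effect-positive draws.
    """
    grid = tuple(result.lambda_grid if lambda_grid is None else lambda_grid)
    if len(grid) == 0:
        raise PSAError("empty lambda grid")
    if len(result.draws) == 0:
        raise PSAError("empty PSA result")
    de = result.draws["delta_e"].to_numpy()
    dc = result.draws["delta_c"].to_numpy()
    probs = [float(np.mean(de * lam - dc > 0.0)) for lam in grid]
    return pd.DataFrame({"lambda": grid, "probability": probs})


# -- deterministic companions ------------------------------------------------


class ScenarioSpec(BaseModel):
    """A named set of parameter overrides applied on top of the base case.

    Override paths use the module's parameter-path syntax and may also
    address analysis settings (``settings.<field>``, e.g. ``settings.lambda``).
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    overrides: dict[str, float] = Field(default_factory=dict)


_SETTINGS_ALIASES = {"lambda": "wtp_lambda"}


def _apply_scenario(
    pair: SpecPair, settings: OutcomeSettings, scenario: ScenarioSpec
) -> tuple[SpecPair, OutcomeSettings]:
    new_pair = pair.copy()
    new_settings = settings.model_copy(deep=True)
    for path, value in scenario.overrides.items():
        if path.startswith("settings."):
            name = path.split(".", 1)[1]
            name = _SETTINGS_ALIASES.get(name, name)
            if name not in OutcomeSettings.model_fields:
                raise PathError(f"scenario '{scenario.name}': unknown setting '{path}'")
            setattr(new_settings, name, value)
        else:
            try:
                assign_parameter(new_pair, path, value)
            except (PathError, ModelValidationError) as exc:
                raise PathError(f"scenario '{scenario.name}': {exc}") from None
    return new_pair, new_settings


def run_scenarios(
    pair: SpecPair,
    scenarios: Sequence[ScenarioSpec],
    settings: OutcomeSettings,
    life_table=None,
) -> pd.DataFrame:
    """Deterministic re-evaluation of consecutive parameter scenarios.

    The base case is included as the first row; scenarios follow in the
    order given.
    """
    all_specs = [ScenarioSpec(name="base_case")] + list(scenarios)
    records = []
    for sc in all_specs:
        sc_pair, sc_settings = _apply_scenario(pair, settings, sc)
        inc = evaluate_pair(sc_pair, sc_settings, life_table).incremental
        records.append(
            {
                "scenario": sc.name,
                "delta_e": inc.delta_e,
                "delta_c": inc.delta_c,
                "icer": inc.icer,
                "inmb": inc.inmb,
                "dominance": inc.dominance,
            }
        )
    return pd.DataFrame.from_records(records)


def one_way_tornado(
    pair: SpecPair,
    distributions: Sequence[ParameterDistribution],
    settings: OutcomeSettings,
    life_table=None,
    fixed_fraction: float = 0.2,
) -> pd.DataFrame:
    """One-way deterministic sensitivity of INMB to each parameter.

    Each parameter is set to its 2.5th and 97.5th percentile (for ``fixed``
    distributions, ±``fixed_fraction`` of the base value) with all others at
    base, and INMB re-computed. Percentile values falling outside the
    target's valid domain are clamped to the boundary (and logged). Rows are
    sorted by INMB range width, widest first.
    """
    base_inmb = evaluate_pair(pair, settings, life_table).incremental.inmb
    records = []
    for dist in distributions:
        base_value = resolve_parameter(pair, dist.target)
        if dist.family == "fixed":
            centre = dist.params["value"]
            low, high = centre * (1 - fixed_fraction), centre * (1 + fixed_fraction)
        else:
            low, high = dist.ppf(0.025), dist.ppf(0.975)
        lo_dom, hi_dom = target_domain(pair, dist.target)
        clamped_low = min(max(low, lo_dom), hi_dom)
        clamped_high = min(max(high, lo_dom), hi_dom)
        if (clamped_low, clamped_high) != (low, high):
            logger.warning(
                "tornado: percentiles of '%s' clamped to domain [%g, %g]",
                dist.target, lo_dom, hi_dom,
            )
        inmbs = []
        for value in (clamped_low, clamped_high):
            candidate = pair.copy()
            assign_parameter(candidate, dist.target, value)
            inmbs.append(evaluate_pair(candidate, settings, life_table).incremental.inmb)
        records.append(
            {
                "target": dist.target,
                "base_value": base_value,
                "low_value": clamped_low,
                "high_value": clamped_high,
                "inmb_low": inmbs[0],
                "inmb_high": inmbs[1],
                "inmb_base": base_inmb,
                "inmb_range": abs(inmbs[1] - inmbs[0]),
            }
        )
    frame = pd.DataFrame.from_records(records)
    if len(frame):
        frame = frame.sort_values(
            "inmb_range", ascending=False, kind="stable"
        ).reset_index(drop=True)
    return frame
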