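# Methods

## Model structure

The engine implements a discrete-time cohort state-transition model. A
model is an ordered set of mutually exclusive health states with exactly
one absorbing state (death); the canonical configuration has three:
baseline health, deteriorated health, death. The cohort is a probability
vector over states; each cycle it is multiplied by a row-stochastic
transition matrix. The matrix diagonal is always the implied residual
(1 minus the competing exits); a negative residual is a hard error naming
the state and cycle, never a silent renormalisation, because renormalising
would mask invalid inputs.

Transitions can be declared as per-cycle probabilities or per-year rates;
rates convert with `p = 1 − exp(−r·Δt)`. Probability-scale values are used
verbatim as per-cycle probabilities (no round trip through rates), so
hand-specified matrices are reproduced exactly.

### Mortality composition

Baseline mortality may be a constant or bound to a life table, looked up
at `floor(start_age + t·Δt)` with no interpolation — interpolating an
annual table under annual cycles adds only spurious precision. Mortality
in the deteriorated state is composed from the baseline hazard on the
rate scale: either additively (`r = r_base + r_excess`, the default,
because added hazards always yield valid probabilities and age dependence
flows through) or as a rate ratio (`r = r_base · RR`). A direct
per-cycle probability is also accepted when the analyst has one.

At a closed life table's terminal age the annual death probability is 1;
any competing exit alongside certain death then triggers the
negative-residual error. Horizons should therefore end before the cohort
reaches the table's closure age (all shipped profiles do).

## Valuation

Per cycle `t ≥ 1` the cohort accrues `occupancy · reward · Δt` discounted
by `(1+r)^{−t·Δt}`, with separate annual rates for effects and costs
(both default 0.03/yr — jurisdictions differ, and the two rates are
independently configurable for that reason). Rewards start at cycle 1 so
the start state is not double-counted. Half-cycle correction (default on)
replaces the cycle-t occupancy with the mean of rows t−1 and t — the
trapezoid rule — correcting the end-of-cycle bias of discrete
transitions; tests that compare against geometric closed forms switch it
off.

Utilities default to the [0, 1] scale anchored at dead = 0 and full
health = 1; a per-model switch extends the admissible range to [−1, 1]
because published EQ-5D value sets contain states worse than dead.
Out-of-bounds utilities are validation errors, except for instrument
mappings, whose predictions are clamped to the bounds and logged
(refusing a mapped value outright would discard usable data; the clamp is
flagged so it can be audited).

Costs are split into a healthcare-payer stream and a societal stream
(social care plus patient-borne costs); the perspective setting selects
healthcare-only or the sum. The intervention's delivery cost has a
one-off component charged at cycle 0 and a per-cycle component discounted
at the cost rate. The per-cycle component is charged for the whole cohort
over the horizon — it models a programme-level running cost (platform
fees, staffing) rather than a per-survivor service; survival-dependent
delivery costs belong in the deteriorated/baseline state costs instead.

ΔE, ΔC, INMB = ΔE·λ − ΔC are always reported; the ICER only in the two
trade-off quadrants of the cost-effectiveness plane. Dominance is
classified from the signs of ΔE and ΔC, with ΔE = 0 resolved by the cost
sign and full equality flagged as equivalence.

## Uncertainty analysis

Each uncertain input is addressed by a path
(`<arm>.transition.<from>.<to>`, `<arm>.utility.<state>`, …; `both.`
writes a shared parameter into both arms) and carries a distribution:
beta for probabilities and utilities, gamma or lognormal for costs and
rates, normal where symmetry is defensible, fixed for known values.
Distributions are parameterised naturally or by (mean, SE) through
method-of-moments fits; an infeasible beta variance (σ² ≥ μ(1−μ)) is an
error, not a clamp.

PSA samples all parameters independently per draw — no correlation
structure in this version, since the evidence base this engine targets
rarely supports estimating one — from a single seeded generator, in
declared parameter order; the order is part of the reproducibility
contract, and identical seeds reproduce draw tables bitwise. Draws that
produce an invalid model (domain violation or negative residual) are
rejected and re-drawn, never clamped, because clamping would silently
distort the input distribution; the analysis aborts if the rejection rate
exceeds 5% (configurable), naming the implicated distributions. The CEAC
reports, per λ, the fraction of draws with ΔE·λ − ΔC > 0, ties counting
as not cost-effective.

Scenario analysis re-evaluates the base case under consecutive override
sets (parameters or settings such as λ), always including the base case
as row 0. The tornado sets each parameter to its 2.5th/97.5th percentile
(±20% for fixed values) with all others at base, clamps percentiles to
the target's valid domain (logged), and sorts by INMB range.

## Synthetic data

`generate_synthetic_fixture` emulates the inputs an analyst would bring:
a national life table and a population/condition-specific parameter set.
Life tables follow a Gompertz hazard `h(a) = α·e^{βa}` (α ≈ 2–3·10⁻⁵,
β ≈ 0.09–0.10), giving annual death probabilities that rise monotonically
from ~10⁻³ in late middle age to ~0.6 at age 110, where the table closes
at 1 — the broad shape of European period life tables. Three profiles set
the study conditions: `generic_elderly` (cohort age 70, incidence of
functional decline 0.08/yr, recovery 0.10/yr, excess mortality 0.03/yr,
utilities 0.84/0.62, the intervention cutting incidence by 25% and excess
mortality by 15% for €400 one-off + €150/yr), `falls_prevention` (age 75,
higher incidence and recovery, a 30% incidence reduction), and
`chronic_disease` (age 60, low recovery, the intervention mainly reducing
excess mortality). Values are deterministically jittered (±5% log-normal)
per seed so different seeds give distinct but equally plausible studies.
Each fixture ships beta/gamma distributions on its key parameters with
SEs of 10–20% of the mean, typical of small pilot evidence.

What the fixtures do **not** emulate: correlated parameters, time-varying
intervention effects, non-adherence and uptake, age- or sex-stratified
utilities and costs, and more than one morbidity state. Passing tests on
these fixtures therefore demonstrates the engine's arithmetic and
contracts, not the realism of any particular evaluation.

## Numerical choices

- Matrix rows are checked to 1e-12, cohort traces to 1e-9 (accumulated
  round-off over long horizons).
- Probability↔rate conversions use `expm1`/`log1p` for small-argument
  accuracy; the round trip is exact to 1e-12 over the working domain.
- The deterministic analyses in the test-suite and acceptance script use
  30-cycle (annual) horizons and 1,000-draw PSAs — enough for CEAC
  estimates with Monte-Carlo SE below 0.016 on a probability.
- Validation is strict-schema throughout (unknown JSON keys rejected);
  parameter files are written in a canonical form (sorted keys) so
  save∘load is byte-identical.

## Known limitations

- Cohort-level (Markov) only: no individual-level simulation, no history
  dependence beyond the current state.
- Structural uncertainty (alternative state topologies) is out of scope;
  only parameter uncertainty is quantified.
- Mapping algorithms are applied, not estimated; obtaining coefficient
  sets is the analyst's task.
- Single currency label, no conversion or inflation adjustment.
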