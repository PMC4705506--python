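# cohortcea

A Markov cohort cost-effectiveness engine for early health-economic
assessment of health and care interventions — preventive programmes,
eHealth services, integrated-care pathways — against a standard-care
comparator. It is aimed at analysts who need a consistent, transparent way
to turn a small set of epidemiological and economic parameters into
incremental QALYs, costs and decision metrics, with uncertainty analysis
built in.

## The model

The core is a discrete-time cohort state-transition (Markov) model with
three mutually exclusive health states — *baseline health*, *deteriorated
health* and *death* (the engine is N-state generic, with exactly one
absorbing state). Four transitions connect them: incidence of the
deteriorated condition, recovery, baseline mortality (optionally bound to
an age-indexed life table), and mortality in the deteriorated state,
composed from baseline mortality plus an excess hazard on the rate scale
(`p = 1 − e^{−rt}` converts between rates and per-cycle probabilities).

Each alive state carries a utility weight `u ∈ [0, 1]` and annual
healthcare and societal costs. Simulating a cohort through both decision
arms and discounting per cycle gives, per cohort member,

- effects `E = Σ_t (1+r_E)^{−t} (x_t · u) Δt` in QALYs (half-cycle
  corrected by default),
- costs `C` analogously with the cost vectors and cost discount rate,

and the incremental summaries ΔE = E₁ − E₀, ΔC = C₁ − C₀ (including the
intervention's delivery cost), the incremental cost-effectiveness ratio
ICER = ΔC/ΔE, and the incremental net monetary benefit
INMB = ΔE·λ − ΔC for a willingness-to-pay λ per QALY.

Parameter uncertainty propagates through probabilistic sensitivity
analysis: each input gets a distribution (beta for probabilities and
utilities, gamma for costs and rates, parameterised naturally or by
mean/SE via method of moments), Monte-Carlo draws re-run both arms, and
the draws summarise into a cost-effectiveness acceptability curve (CEAC).
Deterministic scenario analysis and one-way tornado analysis cover the
cases where consecutive what-if comparisons are more informative. Scores
from other HRQoL instruments can be cross-walked onto EQ-5D utilities via
declared (piecewise-)linear mapping algorithms whose residual standard
error feeds the PSA.

## Worked example

Generate a synthetic parameter set and life table (an elderly population
with an intervention that lowers the incidence of functional decline),
then run the analysis:

```bash
cohortcea fixture --seed 0 --profile generic_elderly --out examples
cohortcea run --config examples/config.json
```

This writes `examples/results/trace.csv` (per-cycle state occupancy for
both arms) and `examples/results/outcomes.json`, whose incremental block
reads:

```json
"incremental": {
  "delta_c": 824.650763838,
  "delta_e": 0.26591892173,
  "dominance": "trade_off_ne_quadrant",
  "icer": 3101.13608491,
  "inmb": 7152.91688806,
  "lambda": 30000.0
}
```

Over a 30-year horizon (3%/yr discounting, societal perspective) the
intervention gains 0.266 QALYs per cohort member at an extra cost of
€825, i.e. €3,101 per QALY gained — far below the €30,000 willingness to
pay, for a net monetary benefit of €7,153 per person. Appending
`--mode psa --draws 1000` adds `psa_draws.csv` and `ceac.csv` (the
probability of cost-effectiveness across λ); `--mode tornado` ranks the
parameters that drive the INMB. The same pipeline is available as a
library API (`three_state_model`, `evaluate_pair`, `run_psa`, `ceac`, …).

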