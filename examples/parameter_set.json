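{
  "control": {
    "cycle_length": 1.0,
    "start_age": 70.0,
    "start_distribution": [
      1.0,
      0.0,
      0.0
    ],
    "state_values": {
      "baseline": {
        "cost_healthcare": 960.64,
        "cost_societal": 337.9,
        "utility": 0.831
      },
      "death": {
        "cost_healthcare": 0.0,
        "cost_societal": 0.0,
        "utility": 0.0
      },
      "deteriorated": {
        "cost_healthcare": 3774.58,
        "cost_societal": 1971.25,
        "utility": 0.6245
      }
    },
    "states": [
      {
        "id": "baseline",
        "is_absorbing": false,
        "label": "Baseline health"
      },
      {
        "id": "deteriorated",
        "is_absorbing": false,
        "label": "Deteriorated health"
      },
      {
        "id": "death",
        "is_absorbing": true,
        "label": "Death"
      }
    ],
    "transitions": [
      {
        "age_dependent": false,
        "excess": "none",
        "excess_relative_to": null,
        "from_state": "baseline",
        "scale": "probability",
        "to_state": "deteriorated",
        "value": 0.079473
      },
      {
        "age_dependent": false,
        "excess": "none",
        "excess_relative_to": null,
        "from_state": "deteriorated",
        "scale": "probability",
        "to_state": "baseline",
        "value": 0.103254
      },
      {
        "age_dependent": true,
        "excess": "none",
        "excess_relative_to": null,
        "from_state": "baseline",
        "scale": "probability",
        "to_state": "death",
        "value": 0.0
      },
      {
        "age_dependent": false,
        "excess": "additive_rate",
        "excess_relative_to": "baseline",
        "from_state": "deteriorated",
        "scale": "rate",
        "to_state": "death",
        "value": 0.030158
      }
    ],
    "utility_bounds": [
      0.0,
      1.0
    ]
  },
  "distributions": [
    {
      "family": "beta",
      "mean": 0.079473,
      "params": {
        "alpha": 91.97322700000002,
        "beta": 1065.3157516468364
      },
      "se": 0.0079473,
      "target": "control.transition.baseline.deteriorated",
      "truncation": null
    },
    {
      "family": "beta",
      "mean": 0.059605,
      "params": {
        "alpha": 93.9805260878169,
        "beta": 1482.7416631214255
      },
      "se": 0.00596048,
      "target": "intervention.transition.baseline.deteriorated",
      "truncation": null
    },
    {
      "family": "gamma",
      "mean": 0.030158,
      "params": {
        "scale": 0.0012063199999999999,
        "shape": 25.000000000000004
      },
      "se": 0.0060316,
      "target": "control.transition.deteriorated.death",
      "truncation": null
    },
    {
      "family": "beta",
      "mean": 0.6245,
      "params": {
        "alpha": 90.90368367187499,
        "beta": 54.65866007812498
      },
      "se": 0.04,
      "target": "both.utility.deteriorated",
      "truncation": null
    },
    {
      "family": "gamma",
      "mean": 3774.58,
      "params": {
        "scale": 84.92805000000001,
        "shape": 44.44444444444444
      },
      "se": 566.187,
      "target": "control.cost_healthcare.deteriorated",
      "truncation": null
    },
    {
      "family": "gamma",
      "mean": 3585.85,
      "params": {
        "scale": 80.68162500000003,
        "shape": 44.444444444444436
      },
      "se": 537.8775,
      "target": "intervention.cost_healthcare.deteriorated",
      "truncation": null
    }
  ],
  "intervention": {
    "cycle_length": 1.0,
    "start_age": 70.0,
    "start_distribution": [
      1.0,
      0.0,
      0.0
    ],
    "state_values": {
      "baseline": {
        "cost_healthcare": 960.64,
        "cost_societal": 337.9,
        "utility": 0.831
      },
      "death": {
        "cost_healthcare": 0.0,
        "cost_societal": 0.0,
        "utility": 0.0
      },
      "deteriorated": {
        "cost_healthcare": 3585.85,
        "cost_societal": 1971.25,
        "utility": 0.6245
      }
    },
    "states": [
      {
        "id": "baseline",
        "is_absorbing": false,
        "label": "Baseline health"
      },
      {
        "id": "deteriorated",
        "is_absorbing": false,
        "label": "Deteriorated health"
      },
      {
        "id": "death",
        "is_absorbing": true,
        "label": "Death"
      }
    ],
    "transitions": [
      {
        "age_dependent": false,
        "excess": "none",
        "excess_relative_to": null,
        "from_state": "baseline",
        "scale": "probability",
        "to_state": "deteriorated",
        "value": 0.059605
      },
      {
        "age_dependent": false,
        "excess": "none",
        "excess_relative_to": null,
        "from_state": "deteriorated",
        "scale": "probability",
        "to_state": "baseline",
        "value": 0.103254
      },
      {
        "age_dependent": true,
        "excess": "none",
        "excess_relative_to": null,
        "from_state": "baseline",
        "scale": "probability",
        "to_state": "death",
        "value": 0.0
      },
      {
        "age_dependent": false,
        "excess": "additive_rate",
        "excess_relative_to": "baseline",
        "from_state": "deteriorated",
        "scale": "rate",
        "to_state": "death",
        "value": 0.025634
      }
    ],
    "utility_bounds": [
      0.0,
      1.0
    ]
  },
  "intervention_cost": {
    "one_off": 400.0,
    "per_cycle": 150.0
  },
  "metadata": {
    "condition": "age-related functional decline",
    "currency": "EUR",
    "population": "synthetic_generic_elderly",
    "provenance": "default",
    "source": "cohortcea synthetic fixture generator (seed 0)"
  },
  "schema_version": 1,
  "user_overridden": []
}
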