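{
  "life_table": "life_table.csv",
  "mode": "deterministic",
  "out_dir": "results",
  "parameter_set": "parameter_set.json",
  "seed": 0,
  "settings": {
    "currency": "EUR",
    "cycle_length": 1.0,
    "discount_rate_costs": 0.03,
    "discount_rate_effects": 0.03,
    "half_cycle_correction": true,
    "horizon_cycles": 30,
    "lambda": 30000.0,
    "perspective": "societal"
  }
}
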