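{
  "fig5-lowfuel": {
    "module": "side",
    "overrides": {"c0": 0.6, "Nx": 256, "Nz": 64, "t_end": 2.8},
    "expected": "settled",
    "note": "fuel below the neutral level: the drop never lifts off"
  },
  "fig5-midfuel": {
    "module": "side",
    "overrides": {"c0": 0.8, "Nx": 256, "Nz": 64, "t_end": 2.8},
    "expected": "settled",
    "note": "marginal fuel: brief rise, then settles before reaching the top"
  },
  "fig5-default": {
    "module": "side",
    "overrides": {"c0": 1.2, "Nx": 256, "Nz": 64, "t_end": 2.8},
    "expected": "three-stage",
    "note": "rich fuel: ascend, spread along the top, sink as plumes"
  },
  "fig6-dynamic": {
    "module": "confined",
    "overrides": {"beta": 12.0, "eps": 0.05, "N": 256, "t_end": 6.0},
    "expected": "dynamic-aggregates",
    "note": "weak confinement: aggregates keep rearranging"
  },
  "fig6-medium": {
    "module": "confined",
    "overrides": {"beta": 12.0, "eps": 0.03, "N": 256, "t_end": 6.0},
    "expected": "dynamic-aggregates",
    "note": "intermediate confinement"
  },
  "fig6-frozen": {
    "module": "confined",
    "overrides": {"beta": 20.0, "eps": 0.01, "N": 256, "t_end": 6.0},
    "expected": "localized",
    "note": "strong confinement: the pattern barely changes"
  }
}
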