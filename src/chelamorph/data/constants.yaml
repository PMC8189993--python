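# Versioned numeric constants of the reference analysis.
# The nomogram weights and normalisers are frozen constants of the original
# fit over the 47 reference species; they are data, never re-derived.
condyle_inflation: 1.1
adductor_shaft_fraction: 0.5
typical:
  IL: {mean: 216.42, sd: 2.995}
  L1U: {mean: 12.66, sd: 0.238}
  L2M: {mean: 26.45, sd: 0.239}
  CHI: {mean: 51.59, sd: 0.621}
  CLI: {mean: 98.17, sd: 0.689}
  F2AV: {mean: 926.53, sd: 33.228}
  VR: {mean: 0.478, sd: 0.009}
nomogram:
  normaliser1: 5.48
  normaliser2: 1.81
  score1_weights: {IL: 0.525, L1U: 0.889, L2M: 0.927, CHI: 0.954, CLI: 0.906, F2AV: 0.925}
  score2_weights: {IL: -0.796, L1U: 0.333, L2M: 0.010, CHI: 0.104, CLI: -0.200, F2AV: 0.216}
bands:
  toughness: [1039.0, 2642.7, 3807.0]
  velocity_ratio: [0.276, 0.5, 0.65]
  pest_toughness: 1100.6
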