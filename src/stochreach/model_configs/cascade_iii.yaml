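# Wiring iii: feedback system — the output C induces production of A
# (kCA = 0.2) on top of the plain chain of wiring i.
name: cascade_iii
species: [A, B, C]
parameters:
  kAB: 1.0
  kBC: 1.0
  kAC: 0.0
  kCA: 0.2
  kdeg: 0.8
reactions:
  - stoichiometry: [0, 1, 0]
    propensity: kAB*A
  - stoichiometry: [0, 0, 1]
    propensity: kBC*B
  - stoichiometry: [0, 0, 1]
    propensity: kAC*A
  - stoichiometry: [1, 0, 0]
    propensity: kCA*C
  - stoichiometry: [-1, 0, 0]
    propensity: kdeg*A
  - stoichiometry: [0, -1, 0]
    propensity: kdeg*B
  - stoichiometry: [0, 0, -1]
    propensity: kdeg*C
initial:
  means:
    A: [80.0, 120.0]
    B: 0.0
    C: 0.0
reach:
  horizon: 8.0
  step: 0.01
  order_limit: 20
  analysis: lna
nonnegative: [mean_A, mean_B, mean_C, var_A, var_B, var_C]
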