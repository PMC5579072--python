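# Three-species activation chain A -> B -> C (wiring i: no direct A -> C
# shortcut, no feedback).  All species degrade at the same rate; rate
# units are 1 per time unit with time scaled to the macromolecular
# production rate.  Initial A abundance is only known as a range.
name: cascade_i
species: [A, B, C]
parameters:
  kAB: 1.0
  kBC: 1.0
  kAC: 0.0
  kCA: 0.0
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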