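# Controlled two-stage gene expression: transcription switched by an
# external multiplier mu in [0, 1], first-order degradation of mRNA (m)
# and protein (p).  Time is normalized to the protein turnover time;
# k1 is in molecules per time unit, the other rates in 1 per time unit.
# Under constitutive production (mu = 1) the stationary means are
# 20 mRNA and 2000 protein molecules.
name: gene_expression
species: [m, p]
parameters:
  k1: 100.0
  k2: 5.0
  k3: 100.0
  k4: 1.0
reactions:
  - stoichiometry: [1, 0]
    propensity: k1*mu
  - stoichiometry: [-1, 0]
    propensity: k2*m
  - stoichiometry: [0, 1]
    propensity: k3*m
  - stoichiometry: [0, -1]
    propensity: k4*p
input:
  bounds: [0.0, 1.0]
initial:
  means:
    m: 0.0
    p: 0.0
reach:
  horizon: 10.0
  step: 0.01
  order_limit: 20
  analysis: lna
uncertainty:
  - parameter: k4
    delta_fraction: 0.05
nonnegative: [mean_m, mean_p, var_m, var_p]
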