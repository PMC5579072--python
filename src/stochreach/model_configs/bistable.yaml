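# Stem-cell differentiation switch: the Oct4-Sox2 complex (OS)
# auto-activates its own production and drives the stem-cell marker
# Nanog (N), which also auto-activates through a steep (gn = 2) Hill
# term.  The parameter set makes Nanog bistable: a low-Nanog
# (differentiated) and a high-Nanog (stem cell) stable state coexist and
# the initial Nanog level selects the basin.
#
# Covariance coordinates do not feed back into the mean equations here,
# and the analysis question is about average Nanog levels, so the reach
# analysis runs on the deterministic macroscopic subsystem
# (analysis: macroscopic); the declared initial (co)variances are kept
# for reference and for moment-level simulation.  The default initial
# set N0 = 0.6 +/- 0.15 straddles the basin boundary.
name: bistable
species: [OS, N]
parameters:
  k1: 0.03
  k2: 50.0
  k3: 0.1
  k4: 14.0
  kdeg: 1.0
  K: 10.0
  gos: 1.0
  gn: 2.0
reactions:
  - stoichiometry: [1, 0]
    propensity: k1*(k2*OS**gos/((K + OS**gos)*kdeg))**2
  - stoichiometry: [-1, 0]
    propensity: kdeg*OS
  - stoichiometry: [0, 1]
    propensity: k3*OS**gos/(K + OS**gos)
  - stoichiometry: [0, 1]
    propensity: k4*N**gn/(K + N**gn)
  - stoichiometry: [0, -1]
    propensity: kdeg*N
initial:
  means:
    OS: 60.0
    N: [0.45, 0.75]
  covariances:
    var_OS: 10.0
    cov_OS_N: 1.0
    var_N: 0.1
reach:
  horizon: 15.0
  step: 0.01
  order_limit: 20
  analysis: macroscopic
nonnegative: [mean_OS, mean_N]
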