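# Methods

## Scope and model class

`stochreach` computes conservative, set-valued predictions for the
*population statistics* of stochastic biochemical reaction networks: the
time evolution of species means and (co)variances under bounded control
inputs, interval-uncertain rate parameters and nonlinear rate laws.  The
pipeline is

1. close the stochastic model into a deterministic ODE system over
   means and covariances (linear noise approximation, LNA);
2. propagate a zonotopic set of moment states through that ODE system
   step by step, enlarging ("bloating") the set at each step so that it
   provably covers every admissible input value, parameter value and —
   for nonlinear rates — every linearization error.

The result at each grid time is a zonotope in moment space whose
per-coordinate interval hull bounds the achievable means and variances.

## Moment dynamics (LNA)

A network is given by a stoichiometry matrix `S` (species × reactions)
and propensities `F(φ) = [a_1 … a_r]`.  Splitting the copy-number
process into a macroscopic mean `φ` and Gaussian fluctuations closes the
first two moments:

    dφ/dt = S F(φ)
    dΣ/dt = S D Σ + Σ (S D)ᵀ + S diag{F(φ)} Sᵀ,   D = ∂F/∂φ.

The packed state is `x = [φ; (Σ)ᵛ]` with the covariance upper triangle
vectorized row-continuously, `n = N(N+3)/2` coordinates.  For networks
whose propensities are affine in the species (e.g. the gene-expression
and cascade examples) these equations are *exact* moment equations of
the master equation, and the packed system is affine in `x`.  An input
multiplier `mu` placed in designated propensities separates as
`f(x, u) = g(x) + B u` when it enters linearly; `B` is obtained by
symbolic differentiation.

The LNA assumptions (moderately high copy numbers, near-Gaussian
fluctuations) matter only for nonlinear propensities; the engine itself
is agnostic to how the ODE system was produced, and arbitrary systems —
e.g. moment-expansion output with closures, or purely deterministic
models — can be wrapped via `ingest_external_system` (Jacobians are
finite-differenced when not supplied).

All symbolic processing substitutes parameter values as *exact*
rationals/integers before differentiation.  This is not cosmetic: with
symbolic Hill exponents, differentiation leaves removable `x**(g-k)`
poles at zero copy number that evaluate to NaN exactly where wide reach
sets need to be evaluated.

## Linear propagation

For affine dynamics `ẋ = A x + b + B u` on an equidistant grid with step
τ the successor set is

    R_{i+1} = e^{Aτ} R_i ⊕ β_input ⊕ β_δ

with `ψ(A,τ) = A⁻¹(e^{Aτ} − I)`:

* `β_input = (ψ (b + B u_c); ψ B u_d)` for inputs constant over a step
  in `[u_c − u_d, u_c + u_d]`;
* when `A` is numerically singular (condition number above 1e12) `ψ` is
  replaced by its integrated Taylor series of order ν (default 6) and a
  remainder box `β_ν` derived from `e^{|A|τ}` minus the truncated
  series is added — valid for the sub-unit step sizes used throughout;
* `β_δ` covers a rate parameter in `[k̂ − δ, k̂ + δ]`: with
  `D = |A(k̂+δ) − A(k̂)|` (entrywise) and the per-coordinate maximum
  `|x|max` of the current set (elementwise max with a one-step image so
  non-converging runs are not underestimated), the disturbance box
  `diag{D |x|max}` is mapped through ψ like an input.  Independent
  uncertain parameters contribute one such term each (conservative
  superposition).

`e^{Aτ}` and ψ are computed once per run (scaling-and-squaring matrix
exponential).  With a point initial set, no input uncertainty and no
parameter uncertainty the iteration is exact up to matrix-exponential
round-off: centres follow the closed-form flow and no generators are
created.

Interval sets `R_[iτ,(i+1)τ]` start from a conservative hull of `I` and
its one-step image inflated by the standard constants
`α_τ = (e^{τ‖A‖} − 1 − τ‖A‖)·sup_{x∈I}‖x‖` and
`β_τ = (e^{τ‖A‖} − 1)/‖A‖·μ` (infinity norm; the bloat ball realized as
an axis-aligned box), then propagate with the same step operator.  The
parameter bloat is included in the interval iteration as well
(conservative direction).

Generator counts grow by the bloat terms each step; whenever the
zonotope order exceeds the configured limit (default 20) the
smallest-score generators (score `‖g‖₁ − ‖g‖∞`) are collapsed into
their axis-aligned interval hull — the standard conservative reduction.

## Nonlinear propagation

Nonlinear systems are linearized at each step around the current set
centre, giving an affine step plus a bloat `β_ε` for the linearization
error rate `ε(x) = |f(x) − [A_i(x − c_i) + f(c_i)]|`:

    R_{i+1} = (c_i + ψ(A_i,τ) f(c_i); e^{A_i τ} G_i) ⊕ β_ε [⊕ β_input ⊕ β_δ].

`β_ε = M(|A_i|, τ) · diag{ε̂}` where `M` bounds `∫₀^τ |e^{A s}| ds`
entrywise via `|e^{As}| ≤ e^{|A|s}` — the error is treated as a bounded
disturbance integrated over the step, exactly like the input terms.

### The error bound ε̂

`ε̂` must upper-bound `ε` per coordinate over the states visited during
the step; the step set is first inflated by the one-step drift
`τ(|f(c)| + |A| r)` (with `r` the per-coordinate set radius).  Three
monotone estimates are computed and the per-coordinate minimum taken:

* **second order** (Lagrange remainder):
  `½ Σ_{k,l} max|H_j[k,l]| dx_k dx_l` — exact for quadratic right-hand
  sides and tight on step-sized boxes;
* **first order** (Jacobian range):
  `Σ_k max|J_jk(ξ) − J_jk(c)| dx_k` — linear in the set width;
* **zeroth order** (range of the non-affine part): the right-hand side
  is split symbolically into an exact linear part plus `g(x)`;
  `ε_j ≤ (max g_j − min g_j over the hull) + |∇g_j(c)|·dx`.  For
  saturating (Hill-type) rates `g` has bounded range, so this bound —
  and with it the bloat per unit time — stays *finite no matter how
  wide the set grows*.  Without it the quadratic bound feeds back on
  the set width and escapes in finite time on any set spanning two
  attractors.

Derivative maxima over the interval hull are taken on product lattices
that are dense along coordinates in which the Jacobian is genuinely
nonlinear (decided symbolically; covariance coordinates enter the LNA
dynamics bilinearly, so their extrema sit at box corners and only the
corners are evaluated) and refined 9 → 17 → 33 … points per axis until
no entry grows by more than 2 % (the last gain is added as a resolution
margin).  Crucially, the lattices always include the *feature points* of
the rate laws: the real roots of the first four derivatives of every
propensity, solved symbolically once per model.  Hill-type rates have
derivative peaks a few units wide; a plain lattice over a set that has
grown to hundreds of units simply never samples them, and the resulting
under-estimate is not a tolerance issue but a soundness failure
(sampled errors exceed the bound and true trajectories escape the set).
With the feature points injected, sampled linearization errors over
10⁵ probes on the bistable example never exceed ε̂.

This estimator requires symbolic Hessians; for ingested black-box
systems a sampling fallback (maximum sampled error × safety factor 2,
`hessian_bound="sampling"`) is available but is heuristic and not used
by any shipped fixture.

Adaptive stepping (optional) takes the step boundaries from an
error-controlled RK45 integration of the centre trajectory (relative
tolerance 1e-8), capped at 4× the configured base step because the
per-step set bloat grows superlinearly with the step even where the
centre integrator would tolerate long steps.  `e^{A_i τ_i}` is
recomputed each step in the nonlinear case anyway, so variable steps
cost nothing extra.

### Negative values and multistability

Zonotopes are convex and centrally symmetric.  A set forced to enclose
two well-separated stable states therefore also contains the symmetric
counterpart of the high state — including impossible negative copy
numbers.  The propagated sets are never truncated (that would break the
zonotope algebra); instead `clamp_nonnegative_projection` clamps the
*reported* per-coordinate hulls at zero and raises a flag per
coordinate.  The flag doubles as a cheap indicator that the initial set
straddles a basin boundary: in the stem-cell example the straddling run
is flagged while both single-basin runs stay positive throughout.

## Exact simulation oracle

The conservatism claims are checked against the direct-method
stochastic simulation algorithm: exact sample paths of the master
equation, with piecewise-constant input switches treated as hard event
boundaries (waiting times re-drawn; memorylessness makes this exact).
A vectorized ensemble simulator advances all realizations of a
population in lockstep and records states on the reach grid; for the
gene-expression module (linear propensities — the moment ODEs are
exact) population moments must lie inside the reach sets up to sampling
error.  Sampling slack uses distribution-free standard errors computed
from the ensemble's own fourth moments; normal-theory errors understate
the spread of variance estimates at low (Poisson-like) copy numbers and
produce spurious containment failures at 3 SE.

## Model invalidation score

For observations `y` of one species at time `t`, the normalized
distance is `max(0, lower(t) − y, y − upper(t)) / sqrt(max reachable
variance at t)`, where `[lower, upper]` is the species-mean interval
hull of the point-in-time reach set (observation times snap to the
nearest grid point within half the local grid gap, otherwise bounds are
interpolated).  Distances are zero inside the band and are reported per
time point (mean and maximum over replicates); no accept/reject
threshold is hard-coded — the CLI accepts one for convenience, but the
distances themselves are the result.

## Shipped example models and default conditions

* **gene_expression** — controlled two-stage expression; rates
  `k = [100, 5, 100, 1]` (k1 in molecules/t.u., others 1/t.u.; time
  normalized to protein turnover), transcription multiplier
  `mu ∈ [0, 1]`, initial state empty, horizon T = 10, step τ = 0.01,
  optional ±5 % uncertainty in the protein degradation rate k4.
  Stationary means under `mu ≡ 1` are 20 mRNA / 2000 protein;
  stationary variances 20, 1000/3 (covariance) and 106000/3.
* **cascade_i/ii/iii** — three-species activation chain variants used
  in the invalidation example; `k_AB = 1`, `k_deg = 0.8`, variant
  wirings (i) `k_BC = 1`, (ii) `k_BC = 0.1, k_AC = 0.9`,
  (iii) `k_BC = 1, k_CA = 0.2`; initial A ∈ [80, 120], B = C = 0.
  Horizon 8 and six observation times t = 1…6 are this package's
  choice (the dynamics settle within ~8 turnover times and six sampling
  times mirror a sparse time-course experiment).
* **bistable** — Oct4-Sox2 / Nanog differentiation switch,
  `[k1,k2,k3,k4,kdeg,K,γ_OS,γ_N] = [0.03, 50, 0.1, 14, 1, 10, 1, 2]`,
  OS₀ = 60, Nanog windows 0.6±0.15 (straddling), 0.4±0.1 and 2±0.5
  (single-basin), horizon 15, step 0.01.  The analysis runs on the
  deterministic macroscopic subsystem (`analysis: macroscopic`): the
  mean equations are closed in themselves and the question is about
  average Nanog levels.  The declared (co)variance values (10, 1, 0.1)
  are carried in the config for moment-level simulation but not
  propagated — see limitations.

Scaled-down study sizes: the conservatism suite uses 2000 realizations
per signal and 10 random on/off signals in the test suite (5 signals ×
1000 realizations in the acceptance script); tolerances are 3 standard
errors of the estimates, so conclusions are invariant to the population
size chosen.

## What the synthetic data does and does not emulate

The SSA ensembles are exact samples of the assumed models, so
containment checks validate the *propagation machinery*, not the LNA
itself: for the linear-propensity examples the moment ODEs are exact
and containment is a sharp test; for nonlinear rate laws the LNA is an
approximation of the true master equation whose error is not certified
here (the LNA is the model being analysed, not a bound this package
proves).  Real measurement noise, extrinsic variability between cells,
and partial observability are all absent; the validation example's
"measurements" are noise-free reads of single exact trajectories.

## Numerical choices

* Zonotope generator pruning at 1-norm < 1e-12; containment LP slack
  1e-9 (scaled), solved with HiGHS.
* Order limit 20 by default; reduction score `‖g‖₁ − ‖g‖∞`.
* Condition-number threshold 1e12 for the singular-ψ fallback; Taylor
  order 6.
* Matrix exponentials via scipy's scaling-and-squaring.
* Derivative-lattice refinement tolerance 2 %, point budget 20 000.
* Sample covariances with denominator n − 1; RNGs are numpy
  Generators; every stochastic entry point takes a seed and identical
  seeds reproduce bitwise-identical trajectories.

## Known limitations

* Propagating the full 5-coordinate LNA of the bistable model from a
  basin-straddling initial set diverges numerically: the variance
  coordinates' linearized dynamics are genuinely unstable along the
  basin boundary, and conservative bloating amplifies the (unbounded)
  true reachable variance past floating-point range.  The macroscopic
  analysis used by the fixture answers the question the model poses;
  variance bounds in multistable regimes are outside what a single
  convex set can usefully represent.
* The derivative-maxima lattices are exhaustive for rate laws whose
  derivative extrema are captured by the symbolically computed feature
  points (rational/Hill/polynomial rates — everything shipped); for
  ingested black-box systems only the heuristic sampling bound is
  available.
* Inputs are constant over a step; intra-step input variation is
  covered only through the interval sets' inflation, and backward
  reachability / avoid-set verification are not implemented.
* Multi-parameter uncertainty is superposed term by term, which is
  conservative but can be loose when parameters interact strongly.
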