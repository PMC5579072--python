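"""Reachable-set propagation for linear time-invariant moment systems.

The time horizon is partitioned into equal steps tau.  A reachable
zonotope is pushed one step forward by the exact affine flow
``R -> e^{A tau} R`` and Minkowski-summed with bloating sets that account
for everything not captured by the nominal autonomous flow:

* ``beta_mu`` — the effect of a constant-over-step input u in
  [u_c - u_d, u_c + u_d], a drift ``psi(A,tau) B u_c`` plus an
  uncertainty generator ``psi(A,tau) B u_d`` with
  ``psi(A,t) = A^{-1}(e^{At} - I)``;
* ``beta_nu`` — the Taylor-truncation remainder when A is (numerically)
  singular and psi is computed from the integrated Taylor series;
* ``beta_delta`` — interval uncertainty of a rate parameter k in
  [k_hat - delta, k_hat + delta], bounded through the entrywise matrix
  difference |A(k_hat + delta) - A(k_hat)| applied to a per-coordinate
  maximum of the current set.

``e^{A tau}`` and ``psi`` depend only on (A, tau) and are computed once
per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .moment_odes import MomentSystem
from .zonotope import (
    Zonotope,
    affine_map,
    convex_hull_overapprox,
    minkowski_sum,
    reduce_order,
)

__all__ = [
    "ParameterUncertainty",
    "ReachConfig",
    "ReachSequence",
    "psi",
    "psi_abs",
    "input_bloat",
    "param_bloat",
    "reach_step",
    "initial_interval_bloat",
    "reach_sequence",
]

# Condition number above which A is treated as numerically singular and
# psi falls back to the integrated Taylor series.
_COND_THRESHOLD = 1e12


@dataclass
class ParameterUncertainty:
    """Interval-uncertain rate parameter: k in [nominal - delta, nominal + delta]."""

    name: str
    nominal: float
    delta: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class ReachConfig:
    """Run settings for a reachability computation.

    horizon / step are in the model's time units.  The input set is
    ``[input_center - input_halfwidth, input_center + input_halfwidth]``
    (e.g. a multiplier mu in [0, 1] is center 0.5, halfwidth 0.5).
    ``order_limit`` caps the zonotope order via conservative reduction.
    """

    horizon: float
    step: float
    input_center: float = 0.0
    input_halfwidth: float = 0.0
    taylor_order: int = 6
    uncertainties: list[ParameterUncertainty] = field(default_factory=list)
    order_limit: float = 20.0
    interval_sets: bool = True
    adaptive: bool = False
    hessian_bound: str = "corners"  # nonlinearity-bound strategy
    nonnegative: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.horizon < self.step:
            raise ValueError("horizon must be >= step")
        if self.input_halfwidth < 0:
            raise ValueError("input halfwidth must be >= 0")
        if self.taylor_order < 2:
            raise ValueError("taylor_order must be >= 2")

    @property
    def n_steps(self) -> int:
        n = int(round(self.horizon / self.step))
        if abs(n * self.step - self.horizon) > 1e-9 * max(1.0, self.horizon):
            raise ValueError("horizon is not an integer multiple of step")
        return n


@dataclass
class ReachSequence:
    """Time-indexed reachable sets plus per-step diagnostics.

    ``sets[i]`` over-approximates the states reachable exactly at
    ``times[i]``; ``interval_sets[i]`` (when computed) covers the whole
    interval [times[i], times[i+1]].
    """

    times: np.ndarray
    sets: list[Zonotope]
    state_names: list[str]
    interval_sets: list[Zonotope] | None = None
    diagnostics: list[dict] = field(default_factory=list)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def bounds(self, name: str, interval: bool = False):
        """(lower, upper) arrays of one coordinate's interval hull over time."""
        i = self.state_index(name)
        sets = self.interval_sets if interval else self.sets
        lo = np.empty(len(sets))
        hi = np.empty(len(sets))
        for k, Z in enumerate(sets):
            l, u = Z.interval_hull()
            lo[k], hi[k] = l[i], u[i]
        return lo, hi

    def centres(self) -> np.ndarray:
        return np.vstack([Z.centre for Z in self.sets])

    def interval_hulls(self) -> pd.DataFrame:
        """Long-format per-coordinate bounds: time, var, lower, upper."""
        rows = []
        for t, Z in zip(self.times, self.sets):
            lo, hi = Z.interval_hull()
            for name, l, u in zip(self.state_names, lo, hi):
                rows.append((t, name, l, u))
        return pd.DataFrame(rows, columns=["time", "var", "lower", "upper"])

    def write_csv(self, path) -> None:
        self.interval_hulls().to_csv(path, index=False)

    def write_jsonl(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for t, Z in zip(self.times, self.sets):
                rec = {"time": float(t), "kind": "point", **Z.to_dict()}
                fh.write(json.dumps(rec) + "\n")
            if self.interval_sets:
                for t0, t1, Z in zip(
                    self.times[:-1], self.times[1:], self.interval_sets
                ):
                    rec = {
                        "time": [float(t0), float(t1)],
                        "kind": "interval",
                        **Z.to_dict(),
                    }
                    fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# one-step operators
# ---------------------------------------------------------------------------
def psi(A: np.ndarray, t: float, order: int = 6):
    """psi(A, t) = A^{-1}(e^{At} - I) and a Taylor remainder bound.

    For well-conditioned A the closed form is exact and the remainder is
    None.  Numerically singular A falls back to the integrated Taylor
    series  sum_{i=0..order} A^i t^{i+1}/(i+1)!  together with the
    nonnegative remainder matrix  E = e^{|A|t} - sum_{i=0..order}
    (|A| t)^i / i!, which entrywise dominates the truncation error of the
    series for the step sizes used here (t <= 1).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if t <= 0:
        raise ValueError("t must be positive")
    n = A.shape[0]
    eAt = expm(A * t)
    cond = np.linalg.cond(A)
    if np.isfinite(cond) and cond < _COND_THRESHOLD:
        return np.linalg.solve(A, eAt - np.eye(n)), None
    # Taylor fallback
    Psi = np.zeros((n, n))
    term = np.eye(n) * t  # A^i t^{i+1}/(i+1)! at i=0
    for i in range(order + 1):
        Psi += term
        term = term @ A * (t / (i + 2))
    absA = np.abs(A)
    series = np.zeros((n, n))
    term = np.eye(n)  # |A|^i t^i / i! at i=0
    for i in range(order + 1):
        series += term
        term = term @ absA * (t / (i + 1))
    E = expm(absA * t) - series
    E = np.maximum(E, 0.0)
    return Psi, E


def psi_abs(A: np.ndarray, t: float, order: int = 6) -> np.ndarray:
    """Entrywise bound on int_0^t |e^{As}| ds, via |e^{As}| <= e^{|A|s}.

    Used to map per-step disturbance bounds (parameter/linearization
    error rates) into their integrated effect on the state.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[0]
    absA = np.abs(A)
    M = np.zeros((n, n))
    term = np.eye(n) * t
    for i in range(order + 1):
        M += term
        term = term @ absA * (t / (i + 2))
    series = np.zeros((n, n))
    term = np.eye(n)
    for i in range(order + 1):
        series += term
        term = term @ absA * (t / (i + 1))
    E = np.maximum(expm(absA * t) - series, 0.0)
    return M + t * E


def input_bloat(
    A: np.ndarray,
    tau: float,
    B: np.ndarray | None,
    u_c: float,
    u_d: float,
    order: int = 6,
    drift: np.ndarray | None = None,
) -> Zonotope:
    """One-step input effect: drift psi B u_c plus uncertainty psi B u_d.

    ``drift`` is an optional constant forcing term (an affine offset b of
    the dynamics), handled identically to B u_c.  When the Taylor
    fallback of psi was used, the remainder bound beta_nu is folded in as
    an axis-aligned box.
    """
    if u_d < 0:
        raise ValueError("u_d must be >= 0")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n = A.shape[0]
    Psi, E = psi(A, tau, order)
    force_c = np.zeros(n)
    force_abs = np.zeros(n)
    if drift is not None:
        drift = np.asarray(drift, dtype=float).ravel()
        force_c = force_c + drift
        force_abs = force_abs + np.abs(drift)
    gens = []
    if B is not None:
        Bv = np.asarray(B, dtype=float).reshape(n, -1)
        force_c = force_c + (Bv * u_c).sum(axis=1)
        force_abs = force_abs + (np.abs(Bv) * (abs(u_c) + u_d)).sum(axis=1)
        if u_d > 0:
            gens.append(Psi @ (Bv * u_d))
    centre = Psi @ force_c
    if E is not None:
        # beta_nu: remainder of the truncated series applied to the forcing
        half = E @ force_abs
        if np.any(half > 0):
            gens.append(np.diag(half))
    G = np.hstack(gens) if gens else np.zeros((n, 0))
    return Zonotope(centre, G).prune()


def param_bloat(
    A_nominal: np.ndarray,
    A_perturbed: np.ndarray,
    Psi: np.ndarray,
    R_current: Zonotope,
    eAtau: np.ndarray,
) -> Zonotope:
    """Bloating set for an interval-uncertain rate parameter.

    ``D_unc = |A(k_hat + delta) - A(k_hat)|`` bounds the dynamics
    difference; applied to a per-coordinate maximum of the current set
    (and of a rough one-step image, so non-converging runs are not
    underestimated) it yields a zero-centred disturbance box that is
    mapped through psi like a constant-over-step input.
    """
    D_unc = np.abs(
        np.asarray(A_perturbed, dtype=float) - np.asarray(A_nominal, dtype=float)
    )
    if not np.any(D_unc):
        return Zonotope.point(np.zeros(R_current.dimension))
    xmax_now = np.abs(R_current.centre) + R_current.support_radius()
    xmax_next = np.abs(np.asarray(eAtau) @ xmax_now)
    xmax = np.maximum(xmax_now, xmax_next)
    half = D_unc @ xmax
    return Zonotope(np.zeros(half.size), Psi @ np.diag(half)).prune()


def reach_step(
    R: Zonotope,
    eAtau: np.ndarray,
    bloats: list[Zonotope] | None = None,
    order_limit: float | None = None,
) -> Zonotope:
    """R_{i+1} = (e^{A tau} c; e^{A tau} G) ⊕ beta_mu ⊕ beta_delta [⊕ ...]."""
    out = affine_map(eAtau, R)
    for b in bloats or []:
        out = minkowski_sum(out, b)
    if order_limit is not None:
        out = reduce_order(out, order_limit)
    return out


def initial_interval_bloat(
    I: Zonotope,
    A: np.ndarray,
    tau: float,
    mu_bound: float,
    R_tau: Zonotope | None = None,
    order: int = 6,
) -> Zonotope:
    """Zonotope containing every solution point on [0, tau] starting in I.

    Built as the conservative hull of I and its one-step image, inflated
    by an axis-aligned box of radius alpha_tau + beta_tau where (infinity
    norm throughout)

        alpha_tau = (e^{tau ||A||} - 1 - tau ||A||) * sup_{x in I} ||x||
        beta_tau  = (e^{tau ||A||} - 1) / ||A|| * mu_bound

    ``mu_bound`` bounds the forcing norm ||B u + b||_inf over admissible
    inputs.  ``R_tau``, when given, is the already-bloated set at time
    tau (input drift included); otherwise e^{A tau} I is used.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    nrmA = np.linalg.norm(A, np.inf)
    lo, hi = I.interval_hull()
    sup_x = max(np.max(np.abs(lo), initial=0.0), np.max(np.abs(hi), initial=0.0))
    if nrmA > 0:
        e = np.exp(tau * nrmA)
        alpha = (e - 1.0 - tau * nrmA) * sup_x
        beta = (e - 1.0) / nrmA * mu_bound
    else:
        alpha = 0.0
        beta = tau * mu_bound
    if R_tau is None:
        R_tau = affine_map(expm(A * tau), I)
    hull = convex_hull_overapprox(I, R_tau)
    r = alpha + beta
    if r <= 0:
        return hull
    box = Zonotope(np.zeros(I.dimension), np.eye(I.dimension) * r)
    return minkowski_sum(hull, box)


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------
def reach_sequence(
    sys: MomentSystem, I: Zonotope, cfg: ReachConfig
) -> ReachSequence:
    """Propagate I over the whole horizon of a linear(affine) system."""
    if not sys.is_affine:
        raise ValueError(
            "system is not affine in the state; use the nonlinear engine "
            "(reach_nonlinear.reach_sequence_nonlinear)"
        )
    if I.dimension != sys.n:
        raise ValueError("initial set dimension != system dimension")

    A, b = sys.affine_system()
    B = sys.input_matrix
    tau = cfg.step
    n_steps = cfg.n_steps
    eAtau = expm(A * tau)
    Psi, _ = psi(A, tau, cfg.taylor_order)
    beta_in = input_bloat(
        A, tau, B, cfg.input_center, cfg.input_halfwidth, cfg.taylor_order, drift=b
    )

    # perturbed matrices for each uncertain parameter (constant per run)
    perturbed = []
    for unc in cfg.uncertainties:
        Ap, _bp = sys.affine_system(param_overrides={unc.name: unc.nominal + unc.delta})
        perturbed.append(Ap)

    def step_bloats(R: Zonotope) -> list[Zonotope]:
        bl = [beta_in]
        for Ap in perturbed:
            bl.append(param_bloat(A, Ap, Psi, R, eAtau))
        return bl

    times = np.arange(n_steps + 1) * tau
    sets = [I.prune()]
    diagnostics: list[dict] = []
    interval_sets: list[Zonotope] | None = [] if cfg.interval_sets else None

    # forcing bound for the [0, tau] initialization constants
    force_abs = np.abs(b)
    if B is not None:
        force_abs = force_abs + (
            np.abs(B) * (abs(cfg.input_center) + cfg.input_halfwidth)
        ).sum(axis=1)
    mu_bound = float(np.max(force_abs, initial=0.0))

    R = sets[0]
    R_int = None
    for i in range(n_steps):
        bloats = step_bloats(R)
        R_next = reach_step(R, eAtau, bloats, cfg.order_limit)
        if interval_sets is not None:
            if i == 0:
                R_int = initial_interval_bloat(
                    R, A, tau, mu_bound, R_tau=R_next, order=cfg.taylor_order
                )
            else:
                R_int = reach_step(R_int, eAtau, step_bloats(R_int), cfg.order_limit)
            interval_sets.append(R_int)
        diagnostics.append(_step_diag(i, R_next, bloats, sys, cfg))
        sets.append(R_next)
        R = R_next

    return ReachSequence(times, sets, sys.state_names, interval_sets, diagnostics)


def _step_diag(
    i: int, R: Zonotope, bloats: list[Zonotope], sys: MomentSystem, cfg: ReachConfig
) -> dict:
    lo, _hi = R.interval_hull()
    neg = []
    for name in cfg.nonnegative:
        k = sys.state_names.index(name)
        if lo[k] < 0:
            neg.append(name)
    return {
        "step": i,
        "order": R.order,
        "bloat_radii": [float(b.support_radius().max(initial=0.0)) for b in bloats],
        "negative_coords": neg,
    }
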