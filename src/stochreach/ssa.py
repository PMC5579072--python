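"""Exact stochastic simulation (Gillespie direct method) and population moments.

Sample paths of the chemical master equation serve as the independent
check on the reachability engine: population means and covariances
estimated from many exact realizations must fall inside the computed
reach sets (up to Monte-Carlo error) for any admissible input signal.

Piecewise-constant input signals are handled by treating every switch
time as a hard event boundary: propensities are re-evaluated and the
waiting time re-drawn at each switch, which is exact because the
exponential waiting time is memoryless.

Two simulation paths are provided: a plain single-trajectory simulator,
and a vectorized ensemble simulator that advances all realizations of a
population in lockstep (one jump per realization per sweep) and
accumulates moment statistics on a fixed time grid — orders of magnitude
faster for the population sizes used in the conservatism checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .moment_odes import INPUT_SYMBOL, ReactionNetwork, SymbolicMomentSystem

__all__ = [
    "PiecewiseConstantSignal",
    "SSATrajectory",
    "PopulationTrajectory",
    "random_onoff_signal",
    "ssa_simulate",
    "simulate_population",
    "population_moments",
]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PiecewiseConstantSignal:
    """Input u(t): value ``values[k]`` on [breaks[k], breaks[k+1]).

    ``breaks`` has one more entry than ``values``; the last break is the
    end of the definition range (the final value extends beyond it).
    """

    breaks: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.breaks, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if b.size != v.size + 1:
            raise ValueError("breaks must have len(values) + 1 entries")
        if np.any(np.diff(b) <= 0):
            raise ValueError("breaks must be strictly increasing")
        object.__setattr__(self, "breaks", b)
        object.__setattr__(self, "values", v)

    @staticmethod
    def constant(value: float, t_end: float) -> "PiecewiseConstantSignal":
        return PiecewiseConstantSignal(np.array([0.0, t_end]), np.array([value]))

    def value(self, t):
        """Signal value at time(s) t (vectorized)."""
        idx = np.searchsorted(self.breaks, t, side="right") - 1
        idx = np.clip(idx, 0, self.values.size - 1)
        return self.values[idx]

    def next_switch(self, t):
        """First break strictly after t; +inf when none remains."""
        idx = np.searchsorted(self.breaks, t, side="right")
        out = np.where(
            idx < self.breaks.size, self.breaks[np.minimum(idx, self.breaks.size - 1)],
            np.inf,
        )
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PiecewiseConstantSignal)
            and self.breaks.shape == other.breaks.shape
            and np.array_equal(self.breaks, other.breaks)
            and np.array_equal(self.values, other.values)
        )


def random_onoff_signal(
    period: float, t_end: float, seed, levels=(0.0, 1.0)
) -> PiecewiseConstantSignal:
    """On/off signal switching every ``period``, levels drawn uniformly.

    Reproducible for a given seed; the same signal object is shared by
    every realization of a population.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    rng = _as_rng(seed)
    n = max(1, int(np.ceil(t_end / period - 1e-12)))
    values = rng.choice(np.asarray(levels, dtype=float), size=n)
    breaks = np.minimum(np.arange(n + 1) * period, t_end)
    breaks[-1] = t_end
    return PiecewiseConstantSignal(breaks, values)


# ---------------------------------------------------------------------------
# propensity evaluation
# ---------------------------------------------------------------------------
def _propensity_fn(net: ReactionNetwork):
    """Vectorizable propensity evaluator: (X (m, N), mu) -> (m, r)."""
    phi = net.species_symbols()
    mu = sp.Symbol(INPUT_SYMBOL, real=True)
    exact = {
        sp.Symbol(k, real=True): SymbolicMomentSystem._exact(v)
        for k, v in net.parameters.items()
    }
    F = sp.Matrix(net.propensity_exprs()).subs(exact)
    funcs = [sp.lambdify(phi + [mu], e, "numpy") for e in F]

    def evaluate(X: np.ndarray, mu_val) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = [X[:, i] for i in range(X.shape[1])]
        out = np.empty((X.shape[0], len(funcs)))
        for j, fn in enumerate(funcs):
            out[:, j] = np.broadcast_to(fn(*cols, mu_val), X.shape[0])
        return out

    return evaluate


@dataclass
class SSATrajectory:
    """One exact realization: jump times and post-jump states."""

    times: np.ndarray  # (k,)
    states: np.ndarray  # (k, N)
    species: list[str]
    signal: PiecewiseConstantSignal
    seed: object = None

    def at(self, grid) -> np.ndarray:
        """States sampled at grid times (piecewise-constant forward fill)."""
        grid = np.asarray(grid, dtype=float)
        idx = np.searchsorted(self.times, grid, side="right") - 1
        if np.any(idx < 0):
            raise ValueError("grid time before trajectory start")
        return self.states[idx]


@dataclass
class PopulationTrajectory:
    """Population statistics on a time grid.

    ``mean`` is (len(grid), N); ``cov`` is (len(grid), N, N), sample
    covariance with denominator n-1.  ``states`` (n, len(grid), N), when
    kept, holds the individual realizations and enables
    distribution-free standard errors of the moment estimates.
    """

    grid: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    n_realizations: int
    species: list[str]
    signal: PiecewiseConstantSignal
    seed: object = None
    states: np.ndarray | None = None

    @property
    def var(self) -> np.ndarray:
        return np.diagonal(self.cov, axis1=1, axis2=2)

    def packed_moment_se(self) -> np.ndarray:
        """Standard errors of the packed moment estimates, (G, N(N+3)/2).

        Distribution-free (based on the sample's own fourth moments):
        SE(mean) = sqrt(m2/n); SE(s2) = sqrt((m4 - (n-3)/(n-1) s2^2)/n);
        SE(s_xy) = sqrt((m22 - s_xy^2)/n).  Copy-number distributions at
        low counts are far from Gaussian, so normal-theory standard
        errors would understate the uncertainty of the variance
        estimates.
        """
        if self.states is None:
            raise ValueError("realization states were not kept")
        n = self.n_realizations
        dev = self.states - self.mean  # (n, G, N)
        N = len(self.species)
        pairs = [(i, j) for i in range(N) for j in range(i, N)]
        cols = [np.sqrt(self.var[:, i] / n) for i in range(N)]
        for i, j in pairs:
            if i == j:
                m4 = (dev[:, :, i] ** 4).mean(axis=0)
                s2 = self.cov[:, i, i]
                cols.append(np.sqrt(np.maximum(m4 - (n - 3) / (n - 1) * s2**2, 0) / n))
            else:
                m22 = ((dev[:, :, i] ** 2) * (dev[:, :, j] ** 2)).mean(axis=0)
                cols.append(np.sqrt(np.maximum(m22 - self.cov[:, i, j] ** 2, 0) / n))
        return np.stack(cols, axis=1)

    def packed_moments(self) -> np.ndarray:
        """(len(grid), N(N+3)/2) array in moment-state packing.

        Row layout matches the moment-ODE state: means first, then the
        row-continuous upper triangle of the covariance matrix.
        """
        N = len(self.species)
        pairs = [(i, j) for i in range(N) for j in range(i, N)]
        tri = np.stack([self.cov[:, i, j] for i, j in pairs], axis=1)
        return np.hstack([self.mean, tri])

    def to_frame(self):
        import pandas as pd

        N = len(self.species)
        data = {"time": self.grid}
        for i, s in enumerate(self.species):
            data[f"mean_{s}"] = self.mean[:, i]
        for i, s in enumerate(self.species):
            for j in range(i, N):
                key = f"var_{s}" if i == j else f"cov_{s}_{self.species[j]}"
                data[key] = self.cov[:, i, j]
        return pd.DataFrame(data)


def ssa_simulate(
    net: ReactionNetwork,
    x0,
    signal: PiecewiseConstantSignal,
    t_end: float,
    seed,
) -> SSATrajectory:
    """One exact realization by the direct method.

    ``x0`` are nonnegative integer copy numbers.  Exact in distribution;
    bitwise reproducible for a given seed.
    """
    rng = _as_rng(seed)
    x = np.asarray(x0, dtype=float).ravel()
    if x.size != net.n_species:
        raise ValueError("x0 length != number of species")
    if np.any(x < 0) or np.any(x != np.round(x)):
        raise ValueError("x0 must be nonnegative integers")
    S = net.stoichiometry.T  # (r, N) change vectors
    prop = _propensity_fn(net)

    times = [0.0]
    states = [x.copy()]
    t = 0.0
    while t < t_end:
        a = prop(x[None, :], float(signal.value(t)))[0]
        if np.any(a < -1e-12):
            j_bad = int(np.argmin(a))
            raise RuntimeError(
                f"negative propensity for reaction {j_bad} at state {x}"
            )
        a = np.maximum(a, 0.0)
        a0 = a.sum()
        t_sw = min(float(signal.next_switch(t)), t_end)
        if a0 <= 0:
            t = t_sw
            if t >= t_end:
                break
            continue
        dt = rng.exponential(1.0 / a0)
        if t + dt >= t_sw:
            # jump would cross a switch (or the horizon): advance to the
            # boundary and redraw — memorylessness makes this exact
            t = t_sw
            if t >= t_end:
                break
            continue
        t += dt
        j = int(np.searchsorted(np.cumsum(a), rng.uniform(0.0, a0), side="right"))
        j = min(j, a.size - 1)
        x = x + S[j]
        times.append(t)
        states.append(x.copy())
    return SSATrajectory(
        np.asarray(times), np.asarray(states), list(net.species), signal, seed
    )


def simulate_population(
    net: ReactionNetwork,
    x0,
    signal: PiecewiseConstantSignal,
    t_end: float,
    n_realizations: int,
    grid,
    seed,
) -> PopulationTrajectory:
    """Ensemble of exact realizations with moments accumulated on a grid.

    All realizations share the input signal (as in a population of cells
    exposed to the same stimulus).  Realizations advance one jump per
    sweep, vectorized with numpy across the population; first and second
    moments are accumulated at the grid times each realization passes.
    """
    rng = _as_rng(seed)
    grid = np.asarray(grid, dtype=float)
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations for covariances")
    N = net.n_species
    S_T = net.stoichiometry.T  # (r, N)
    prop = _propensity_fn(net)

    m = n_realizations
    X = np.tile(np.asarray(x0, dtype=float).ravel(), (m, 1))
    t = np.zeros(m)
    kidx = np.zeros(m, dtype=np.int64)  # next grid index to record
    G = grid.size
    states = np.empty((m, G, N))

    def record(rows, knew):
        # grid times in [t_i, t_next_i) see the current state X_i
        adv = rows[knew[rows] > kidx[rows]]
        if adv.size == 0:
            return
        single = adv[knew[adv] - kidx[adv] == 1]
        if single.size:
            states[single, kidx[single]] = X[single]
        multi = adv[knew[adv] - kidx[adv] > 1]
        for i in multi:
            states[i, kidx[i]: knew[i]] = X[i]
        kidx[adv] = knew[adv]

    active = t < t_end
    while np.any(active):
        mu = signal.value(t)  # per-realization (realizations sit at own t)
        a = prop(X, mu)
        if np.any(a < -1e-12):
            i, j = np.argwhere(a < -1e-12)[0]
            raise RuntimeError(
                f"negative propensity for reaction {j} at state {X[i]}"
            )
        a = np.maximum(a, 0.0)
        a0 = a.sum(axis=1)
        t_sw = np.minimum(signal.next_switch(t), t_end)
        dt = rng.exponential(1.0, m) / np.where(a0 > 0, a0, 1.0)
        t_jump = np.where(a0 > 0, t + dt, np.inf)
        fire = active & (t_jump < t_sw)
        t_next = np.where(active, np.where(fire, t_jump, t_sw), t)

        knew = np.searchsorted(grid, t_next, side="left")
        record(np.nonzero(active)[0], knew)

        if np.any(fire):
            rows = np.nonzero(fire)[0]
            u = rng.uniform(0.0, 1.0, rows.size) * a0[rows]
            cum = np.cumsum(a[rows], axis=1)
            j = (cum < u[:, None]).sum(axis=1)
            j = np.minimum(j, S_T.shape[0] - 1)
            X[rows] += S_T[j]
        t = t_next
        active = t < t_end

    # grid times at/after the final time see the final state
    knew_final = np.full(m, G, dtype=np.int64)
    record(np.arange(m), knew_final)

    mean = states.mean(axis=0)
    dev = states - mean
    cov = np.einsum("ngi,ngj->gij", dev, dev) / (m - 1)
    return PopulationTrajectory(
        grid, mean, cov, m, list(net.species), signal, seed, states=states
    )


def population_moments(
    trajectories: list[SSATrajectory], grid
) -> PopulationTrajectory:
    """Unbiased sample mean and covariance of trajectories on a grid."""
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    sig = trajectories[0].signal
    for tr in trajectories[1:]:
        if tr.signal != sig:
            raise ValueError("trajectories have mismatched input signals")
    grid = np.asarray(grid, dtype=float)
    states = np.stack([tr.at(grid) for tr in trajectories])  # (n, G, N)
    mean = states.mean(axis=0)
    dev = states - mean
    cov = np.einsum("ngi,ngj->gij", dev, dev) / (len(trajectories) - 1)
    return PopulationTrajectory(
        grid, mean, cov, len(trajectories), trajectories[0].species, sig,
        states=states,
    )
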