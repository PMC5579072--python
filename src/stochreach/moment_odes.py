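"""Mean–covariance ODE systems derived from stochastic reaction networks.

A reaction network is given by a stoichiometry matrix ``S`` (N species x r
reactions) and propensities ``F = [a_1 ... a_r]``.  The linear noise
approximation splits the copy-number process into a macroscopic mean
``phi`` and Gaussian fluctuations, which closes the moment dynamics:

    dphi/dt   = S F(phi)
    dSigma/dt = S D Sigma + Sigma (S D)^T + S diag{F(phi)} S^T

with ``D = dF/dphi`` the propensity Jacobian.  Means and the
row-continuous upper triangle of ``Sigma`` are packed into one state
vector of length n = N(N+3)/2, and the stacked right-hand side is the
deterministic system the reachability engines propagate.

An input multiplier ``mu`` may appear in designated propensities (e.g.
controlled transcription); when it enters linearly the system separates
as f(x, u) = g(x) + B u with a constant input matrix B.

Arbitrary user-supplied ODE systems (e.g. produced by a moment-expansion
tool, or purely deterministic models) can be wrapped with
:func:`ingest_external_system` and run through the same engines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

__all__ = [
    "ReactionNetwork",
    "MomentSystem",
    "SymbolicMomentSystem",
    "CallableSystem",
    "lna_derive",
    "pack_state",
    "unpack_state",
    "evaluate_rhs",
    "ingest_external_system",
]

INPUT_SYMBOL = "mu"


# ---------------------------------------------------------------------------
# reaction networks
# ---------------------------------------------------------------------------
@dataclass
class ReactionNetwork:
    """Stochastic model as the user writes it.

    ``stoichiometry[i, j]`` is the copy-number change of species i when
    reaction j fires.  Propensities are expression strings over species
    names, parameter names and (optionally) the input multiplier ``mu``.
    Zeroth-order rates carry units of molecules per time unit, all other
    rates 1 per time unit.
    """

    species: list[str]
    stoichiometry: np.ndarray
    propensities: list[str]
    parameters: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        N = len(self.species)
        if self.stoichiometry.shape[0] != N:
            raise ValueError("stoichiometry rows != number of species")
        if self.stoichiometry.shape[1] != len(self.propensities):
            raise ValueError("stoichiometry columns != number of propensities")
        if len(set(self.species)) != N:
            raise ValueError("duplicate species names")
        # parse once; surfaces unknown-symbol errors early
        self._exprs = [self._parse(a) for a in self.propensities]

    # symbol table shared by all expression parsing for this network
    def _namespace(self) -> dict[str, sp.Symbol]:
        ns = {s: sp.Symbol(s, real=True) for s in self.species}
        for p in self.parameters:
            ns[p] = sp.Symbol(p, real=True)
        ns[INPUT_SYMBOL] = sp.Symbol(INPUT_SYMBOL, real=True)
        return ns

    def _parse(self, expr) -> sp.Expr:
        ns = self._namespace()
        e = sp.sympify(expr, locals=ns)
        extra = e.free_symbols - set(ns.values())
        if extra:
            raise ValueError(f"unknown symbols in propensity {expr!r}: {extra}")
        return e

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.propensities)

    def propensity_exprs(self) -> list[sp.Expr]:
        return list(self._exprs)

    def species_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(s, real=True) for s in self.species]

    def uses_input(self) -> bool:
        mu = sp.Symbol(INPUT_SYMBOL, real=True)
        return any(mu in e.free_symbols for e in self._exprs)


# ---------------------------------------------------------------------------
# state packing
# ---------------------------------------------------------------------------
def _triu_indices(N: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(N) for j in range(i, N)]


def pack_state(phi, Sigma, atol: float = 1e-9) -> np.ndarray:
    """[phi; upper triangle of Sigma, row-continuous] of length N(N+3)/2."""
    phi = np.asarray(phi, dtype=float).ravel()
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=float))
    N = phi.size
    if Sigma.shape != (N, N):
        raise ValueError("Sigma shape does not match phi length")
    if np.abs(Sigma - Sigma.T).max(initial=0.0) > atol * max(
        1.0, np.abs(Sigma).max(initial=0.0)
    ):
        raise ValueError("Sigma is not symmetric within tolerance")
    tri = np.array([Sigma[i, j] for i, j in _triu_indices(N)])
    return np.concatenate([phi, tri])


def unpack_state(x, N: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`pack_state`; Sigma comes back exactly symmetric."""
    x = np.asarray(x, dtype=float).ravel()
    n = N * (N + 3) // 2
    if x.size != n:
        raise ValueError(f"state length {x.size} != N(N+3)/2 = {n}")
    phi = x[:N]
    Sigma = np.zeros((N, N))
    for k, (i, j) in enumerate(_triu_indices(N)):
        Sigma[i, j] = Sigma[j, i] = x[N + k]
    return phi, Sigma


# ---------------------------------------------------------------------------
# moment systems
# ---------------------------------------------------------------------------
class MomentSystem:
    """Interface both reachability engines consume.

    Concrete classes provide the right-hand side ``f(x, u)``, its state
    Jacobian, the input matrix ``B`` (when the input enters linearly),
    affinity information, and — when available — Hessians for the
    nonlinearity bound.
    """

    n: int
    state_names: list[str]
    input_matrix: np.ndarray | None  # (n, m) or None
    is_affine: bool
    input_is_linear: bool

    def f(self, x, u: float = 0.0) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def jacobian(self, x, u: float = 0.0, param_overrides=None) -> np.ndarray:
        raise NotImplementedError  # pragma: no cover

    def hessian(self, x, u: float = 0.0) -> np.ndarray | None:
        """(n, n, n) array H[j] = d^2 f_j / dx^2, or None if unavailable."""
        return None

    def jacobian_batch(self, X, u: float = 0.0) -> np.ndarray:
        """(n, n, m) Jacobians at m states (rows of X)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.stack([self.jacobian(x, u) for x in X], axis=-1)

    def hessian_batch(self, X, u: float = 0.0) -> np.ndarray | None:
        """(n, n, n, m) Hessians at m states, or None if unavailable."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = []
        for x in X:
            H = self.hessian(x, u)
            if H is None:
                return None
            out.append(H)
        return np.stack(out, axis=-1)

    def jacobian_curvature_mask(self) -> np.ndarray:
        """Boolean mask of coordinates in which the Jacobian is nonlinear.

        Coordinates where every Jacobian entry is affine (e.g. the
        covariance coordinates of a moment system, which enter the
        dynamics bilinearly) attain derivative extrema over a box at the
        box corners; the others need interior evaluation.  The default
        assumes the worst (all nonlinear).
        """
        return np.ones(self.n, dtype=bool)

    def hull_feature_points(self) -> dict[int, np.ndarray]:
        """Known interior-extremum locations per coordinate (see
        SymbolicMomentSystem); none for generic systems."""
        return {}

    def nonlinear_part_batch(self, X, u: float = 0.0) -> np.ndarray | None:
        """Values of the non-affine RHS part, or None if not separable."""
        return None

    def nonlinear_jacobian(self, x, u: float = 0.0) -> np.ndarray | None:
        return None

    def affine_system(self, param_overrides=None) -> tuple[np.ndarray, np.ndarray]:
        """Constant (A, b) with f(x, 0) = A x + b; only for affine systems."""
        if not self.is_affine:
            raise ValueError("system is not affine in the state")
        zero = np.zeros(self.n)
        A = self.jacobian(zero, 0.0, param_overrides=param_overrides)
        b = self._f_with_overrides(zero, 0.0, param_overrides)
        return A, b

    def _f_with_overrides(self, x, u, param_overrides):
        if param_overrides:
            raise ValueError("parameter overrides unsupported for this system")
        return self.f(x, u)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)


class SymbolicMomentSystem(MomentSystem):
    """Moment system held symbolically (sympy), with exact Jacobian/Hessian.

    Rate parameters stay symbolic internally so that parameter-uncertainty
    bloating can re-evaluate the dynamics at perturbed values.
    """

    def __init__(
        self,
        f_sym: sp.Matrix,
        state_syms: list[sp.Symbol],
        mu_sym: sp.Symbol,
        param_values: dict[sp.Symbol, float],
        state_names: list[str],
        species_names: list[str] | None = None,
        f_exact: sp.Matrix | None = None,
    ) -> None:
        self.f_sym = sp.Matrix(f_sym)
        self.state_syms = list(state_syms)
        self.mu_sym = mu_sym
        self.param_values = dict(param_values)
        self.state_names = list(state_names)
        self.species_names = list(species_names) if species_names else None
        self.n = len(state_syms)
        if self.f_sym.shape[0] != self.n:
            raise ValueError("RHS length != state dimension")

        # Exact-parameter RHS: parameter values substituted as exact
        # rationals/integers.  The caller may supply a version derived
        # *after* substitution (integer Hill exponents differentiate
        # cleanly, leaving no removable x**(g-k) poles at zero copy
        # numbers); otherwise values are substituted here.
        self._exact_vals = {s: self._exact(v) for s, v in self.param_values.items()}
        if f_exact is not None:
            self._f_exact = sp.Matrix(f_exact)
        else:
            self._f_exact = self.f_sym.subs(self._exact_vals)
        self._jac_sym = self._f_exact.jacobian(self.state_syms)

        # separable input: f(x, u) = g(x) + B u requires df/dmu constant
        dmu = self._f_exact.diff(mu_sym)
        state_set = set(self.state_syms)
        self.input_is_linear = (
            sp.simplify(dmu.diff(mu_sym)) == sp.zeros(self.n, 1)
            and not any(e.free_symbols & state_set for e in dmu)
        )
        if self.input_is_linear:
            B = np.asarray([float(e) for e in dmu], dtype=float).reshape(self.n, 1)
            self.input_matrix = B if np.any(B != 0.0) else None
        else:
            warnings.warn(
                "input multiplier does not enter as a separable linear term; "
                "it is folded into f and no input matrix is exposed",
                stacklevel=3,
            )
            self.input_matrix = None

        # affine in the state iff the Jacobian has no state dependence
        self.is_affine = all(
            not (e.free_symbols & state_set) for e in self._jac_sym
        )

        self._f_num = self._lambdify(self._f_exact)
        self._jac_num = self._lambdify(self._jac_sym)
        self._jac_cache: dict[tuple, object] = {}
        self._f_cache: dict[tuple, object] = {}
        self._hess_num = None
        self._hess_sym: sp.Matrix | None = None
        self._jac_flat = None
        self._hess_flat = None
        self._curvature_mask: np.ndarray | None = None
        self.rate_exprs: list[sp.Expr] | None = None
        self._features: dict[int, np.ndarray] | None = None
        self._fnl_flat = None
        self._fnl_jac = None

    # -- lambdification ----------------------------------------------------
    @staticmethod
    def _exact(v: float):
        # exact rational substitution (Integers for integral values, e.g.
        # Hill exponents) so rational simplification can cancel removable
        # 0/0 factors instead of leaving them for the numeric code
        if float(v).is_integer():
            return sp.Integer(int(v))
        return sp.Rational(str(float(v)))

    def _lambdify(self, expr: sp.Matrix):
        return sp.lambdify([self.state_syms, self.mu_sym], expr, "numpy")

    def _override_vals(self, overrides: dict[str, float]) -> dict:
        vals = dict(self._exact_vals)
        for name, v in overrides.items():
            sym = sp.Symbol(name, real=True)
            if sym not in vals:
                raise KeyError(f"unknown parameter {name!r}")
            vals[sym] = sp.Float(v)
        return vals

    def _f_fn(self, param_overrides):
        if not param_overrides:
            return self._f_num
        key = tuple(sorted(param_overrides.items()))
        if key not in self._f_cache:
            expr = self.f_sym.subs(self._override_vals(param_overrides))
            self._f_cache[key] = self._lambdify(expr)
        return self._f_cache[key]

    def _jac_fn(self, param_overrides):
        if not param_overrides:
            return self._jac_num
        key = tuple(sorted(param_overrides.items()))
        if key not in self._jac_cache:
            expr = self.f_sym.subs(self._override_vals(param_overrides))
            self._jac_cache[key] = self._lambdify(expr.jacobian(self.state_syms))
        return self._jac_cache[key]

    # -- MomentSystem API ----------------------------------------------------
    def f(self, x, u: float = 0.0) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.n:
            raise ValueError("state length mismatch")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite state")
        return np.asarray(self._f_num(x, u), dtype=float).ravel()

    def _f_with_overrides(self, x, u, param_overrides):
        fn = self._f_fn(param_overrides)
        return np.asarray(fn(np.asarray(x, float).ravel(), u), dtype=float).ravel()

    def jacobian(self, x, u: float = 0.0, param_overrides=None) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        J = np.asarray(self._jac_fn(param_overrides)(x, u), dtype=float)
        if not np.all(np.isfinite(J)):
            bad = [
                self.state_names[i]
                for i in range(self.n)
                if not np.all(np.isfinite(J[i]))
            ]
            raise ValueError(f"non-finite Jacobian rows for states {bad}")
        return J.reshape(self.n, self.n)

    def _batch(self, fn, X: np.ndarray, u: float, shape: tuple) -> np.ndarray:
        """Evaluate a flat-list lambdified form at many states at once.

        Returns an array of ``shape + (len(X),)``; constant entries are
        broadcast across the batch.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = [X[:, i] for i in range(self.n)]
        raw = fn(cols, u)  # list of scalars/arrays, row-major
        out = np.empty(shape + (X.shape[0],))
        flat_out = out.reshape(-1, X.shape[0])
        for i, entry in enumerate(raw):
            flat_out[i] = np.broadcast_to(entry, X.shape[0])
        return out

    def jacobian_batch(self, X, u: float = 0.0) -> np.ndarray:
        """(n, n, m) Jacobians at m states (rows of X)."""
        if self._jac_flat is None:
            self._jac_flat = sp.lambdify(
                [self.state_syms, self.mu_sym], list(self._jac_sym), "numpy"
            )
        return self._batch(self._jac_flat, X, u, (self.n, self.n))

    def hessian_batch(self, X, u: float = 0.0) -> np.ndarray:
        """(n, n, n, m) Hessians at m states (rows of X)."""
        if self._hess_flat is None:
            self._hess_flat = sp.lambdify(
                [self.state_syms, self.mu_sym], list(self._ensure_hess_sym()), "numpy"
            )
        return self._batch(self._hess_flat, X, u, (self.n, self.n, self.n))

    def _ensure_hess_sym(self) -> sp.Matrix:
        if self._hess_sym is None:
            comps = [
                sp.hessian(self._f_exact[j], self.state_syms)
                for j in range(self.n)
            ]
            self._hess_sym = sp.Matrix.vstack(*comps)  # (n*n) x n
        return self._hess_sym

    def hessian(self, x, u: float = 0.0) -> np.ndarray:
        if self._hess_num is None:
            self._hess_num = self._lambdify(self._ensure_hess_sym())
        H = np.asarray(
            self._hess_num(np.asarray(x, float).ravel(), u), dtype=float
        )
        return H.reshape(self.n, self.n, self.n)

    def _ensure_nonlinear_part(self):
        """Split f = (linear in x) + g(x); lambdify g and its Jacobian.

        The linearization error of f equals that of g alone, and for
        saturating (Hill-type) rate laws g has bounded range, which
        gives the error bound that stays finite on arbitrarily wide
        sets.
        """
        if self._fnl_flat is not None:
            return
        g_entries = []
        for e in self._f_exact:
            nl = sp.S.Zero
            for term in sp.Add.make_args(sp.expand(e)):
                try:
                    is_linear = term.is_polynomial(*self.state_syms) and (
                        sp.total_degree(term, *self.state_syms) <= 1
                    )
                except sp.PolynomialError:  # pragma: no cover
                    is_linear = False
                if not is_linear:
                    nl += term
            g_entries.append(nl)
        g = sp.Matrix(g_entries)
        self._fnl_flat = sp.lambdify(
            [self.state_syms, self.mu_sym], list(g), "numpy"
        )
        self._fnl_jac = self._lambdify(g.jacobian(self.state_syms))

    def nonlinear_part_batch(self, X, u: float = 0.0) -> np.ndarray:
        """(n, m) values of the non-affine RHS part at m states."""
        self._ensure_nonlinear_part()
        return self._batch(self._fnl_flat, X, u, (self.n,))

    def nonlinear_jacobian(self, x, u: float = 0.0) -> np.ndarray:
        """Jacobian of the non-affine RHS part at one state."""
        self._ensure_nonlinear_part()
        J = np.asarray(
            self._fnl_jac(np.asarray(x, float).ravel(), u), dtype=float
        )
        return J.reshape(self.n, self.n)

    def hull_feature_points(self) -> dict[int, np.ndarray]:
        """Per-coordinate locations of rate-law derivative extrema.

        All nonlinearity of a moment system enters through the rate
        expressions; the interior extrema of Jacobian/Hessian entries
        over a box therefore sit at real roots of the rates' successive
        derivatives (computed symbolically, once per system).  Bound
        estimators insert these values into their evaluation lattices so
        that narrow derivative peaks inside very wide sets are never
        missed.
        """
        if self._features is not None:
            return self._features
        feats: dict[int, np.ndarray] = {}
        exprs = self.rate_exprs if self.rate_exprs is not None else list(self._f_exact)
        exprs = [e.subs(self.mu_sym, 1) for e in exprs]
        for i, s in enumerate(self.state_syms):
            vals: set[float] = set()
            for e in exprs:
                if s not in e.free_symbols:
                    continue
                d = e
                for _ in range(4):
                    d = sp.diff(d, s)
                    num = sp.numer(sp.together(d))
                    if num.free_symbols - {s}:
                        continue  # multivariate coefficient; lattice covers
                    try:
                        poly = sp.Poly(num, s)
                    except sp.PolynomialError:
                        continue
                    if poly.degree() < 1 or poly.degree() > 16:
                        continue
                    for r in sp.real_roots(poly):
                        vals.add(float(r))
            if vals:
                feats[i] = np.array(sorted(vals))
        self._features = feats
        return feats

    def jacobian_curvature_mask(self) -> np.ndarray:
        if self._curvature_mask is None:
            mask = np.zeros(self.n, dtype=bool)
            for l, s in enumerate(self.state_syms):
                d2 = self._jac_sym.diff(s, 2)
                mask[l] = any(sp.simplify(e) != 0 for e in d2)
            self._curvature_mask = mask
        return self._curvature_mask

    @property
    def n_species(self) -> int | None:
        return len(self.species_names) if self.species_names else None


class CallableSystem(MomentSystem):
    """Wrapper for externally supplied ODE right-hand sides."""

    def __init__(
        self,
        f,
        n: int,
        jac=None,
        input_matrix=None,
        state_names=None,
        is_affine: bool = False,
        hess=None,
        fd_step: float = 1e-6,
    ) -> None:
        self._f = f
        self.n = int(n)
        self._jac = jac
        self._hess = hess
        self._fd_step = fd_step
        if input_matrix is not None:
            input_matrix = np.asarray(input_matrix, dtype=float).reshape(self.n, -1)
        self.input_matrix = input_matrix
        self.input_is_linear = input_matrix is not None
        self.state_names = (
            list(state_names) if state_names else [f"x{i}" for i in range(self.n)]
        )
        if len(self.state_names) != self.n:
            raise ValueError("state_names length != dimension")
        self.is_affine = bool(is_affine)
        # probe the callable once for shape consistency
        out = np.asarray(self._f(np.zeros(self.n), 0.0), dtype=float).ravel()
        if out.size != self.n:
            raise ValueError(
                f"f returned length {out.size}, expected {self.n}"
            )

    def f(self, x, u: float = 0.0) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.n:
            raise ValueError("state length mismatch")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite state")
        return np.asarray(self._f(x, u), dtype=float).ravel()

    def jacobian(self, x, u: float = 0.0, param_overrides=None) -> np.ndarray:
        if param_overrides:
            raise ValueError("parameter overrides unsupported for ingested systems")
        x = np.asarray(x, dtype=float).ravel()
        if self._jac is not None:
            return np.asarray(self._jac(x, u), dtype=float).reshape(self.n, self.n)
        # central differences, step scaled by coordinate magnitude
        J = np.empty((self.n, self.n))
        for k in range(self.n):
            h = self._fd_step * max(1.0, abs(x[k]))
            xp, xm = x.copy(), x.copy()
            xp[k] += h
            xm[k] -= h
            J[:, k] = (self.f(xp, u) - self.f(xm, u)) / (2 * h)
        return J

    def hessian(self, x, u: float = 0.0):
        if self._hess is None:
            return None
        return np.asarray(self._hess(x, u), dtype=float).reshape(
            self.n, self.n, self.n
        )


# ---------------------------------------------------------------------------
# derivation
# ---------------------------------------------------------------------------
def lna_derive(net: ReactionNetwork) -> SymbolicMomentSystem:
    """Derive the packed mean–covariance ODE system of a network.

    Returns a :class:`SymbolicMomentSystem` whose right-hand side stacks
    the mean equations over the vectorized covariance equations in the
    row-continuous upper-triangle order.
    """
    N = net.n_species
    phi = net.species_symbols()
    F = sp.Matrix(net.propensity_exprs())
    S = sp.Matrix(net.stoichiometry)

    pairs = _triu_indices(N)
    sig = {}
    for i, j in pairs:
        s = sp.Symbol(f"_sig_{i}_{j}", real=True)
        sig[(i, j)] = s
        sig[(j, i)] = s
    Sigma = sp.Matrix(N, N, lambda i, j: sig[(i, j)])

    def stacked_rhs(Fv: sp.Matrix) -> sp.Matrix:
        D = Fv.jacobian(phi)
        dphi = S * Fv
        SD = S * D
        dSigma = SD * Sigma + Sigma * SD.T + S * sp.diag(*Fv) * S.T
        return sp.Matrix(
            list(dphi) + [sp.expand(dSigma[i, j]) for i, j in pairs]
        )

    rhs = stacked_rhs(F)
    # same derivation with exact parameter values substituted *before*
    # differentiation; see SymbolicMomentSystem for why
    exact_vals = {
        sp.Symbol(k, real=True): SymbolicMomentSystem._exact(v)
        for k, v in net.parameters.items()
    }
    rhs_exact = stacked_rhs(F.subs(exact_vals))

    state_syms = list(phi) + [sig[p] for p in pairs]

    state_names = [f"mean_{s}" for s in net.species]
    for i, j in pairs:
        if i == j:
            state_names.append(f"var_{net.species[i]}")
        else:
            state_names.append(f"cov_{net.species[i]}_{net.species[j]}")

    mu = sp.Symbol(INPUT_SYMBOL, real=True)
    params = {
        sp.Symbol(k, real=True): float(v) for k, v in net.parameters.items()
    }
    sys = SymbolicMomentSystem(
        rhs, state_syms, mu, params, state_names, net.species, f_exact=rhs_exact
    )
    sys.rate_exprs = list(F.subs(exact_vals))
    return sys


def macroscopic_system(net: ReactionNetwork) -> SymbolicMomentSystem:
    """Deterministic macroscopic subsystem: dphi/dt = S F(phi) only.

    The mean equations of the moment expansion are closed in
    themselves, so reachability questions about average behaviour (e.g.
    basins of attraction of a bistable switch) can be analysed on this
    N-dimensional system directly, without carrying the covariance
    coordinates.
    """
    phi = net.species_symbols()
    F = sp.Matrix(net.propensity_exprs())
    S = sp.Matrix(net.stoichiometry)
    rhs = S * F
    exact_vals = {
        sp.Symbol(k, real=True): SymbolicMomentSystem._exact(v)
        for k, v in net.parameters.items()
    }
    rhs_exact = S * F.subs(exact_vals)
    mu = sp.Symbol(INPUT_SYMBOL, real=True)
    params = {
        sp.Symbol(k, real=True): float(v) for k, v in net.parameters.items()
    }
    sys = SymbolicMomentSystem(
        rhs,
        list(phi),
        mu,
        params,
        [f"mean_{s}" for s in net.species],
        net.species,
        f_exact=rhs_exact,
    )
    sys.rate_exprs = list(F.subs(exact_vals))
    return sys


def evaluate_rhs(sys: MomentSystem, x, u: float = 0.0) -> np.ndarray:
    """Numeric right-hand side dx/dt = f(x, u)."""
    return sys.f(x, u)


def ingest_external_system(
    f,
    n: int,
    jac=None,
    input_matrix=None,
    state_names=None,
    is_affine: bool = False,
    hess=None,
) -> CallableSystem:
    """Wrap an arbitrary ODE system for the reachability engines.

    ``f(x, u) -> dx/dt`` may come from any equation-generation route
    (moment expansion output, deterministic models, hand-written
    dynamics).  When ``jac`` is absent it is finite-differenced; without
    ``hess`` the nonlinear engine falls back to its sampling-based
    nonlinearity bound.
    """
    return CallableSystem(
        f,
        n,
        jac=jac,
        input_matrix=input_matrix,
        state_names=state_names,
        is_affine=is_affine,
        hess=hess,
    )
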