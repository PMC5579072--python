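"""Zonotopes: the set representation used throughout the reachability engine.

A zonotope is a centrally symmetric convex polytope written as a centre
``c`` plus a generator matrix ``G`` whose columns span line segments:

    Z = { c + sum_i a_i g_i : -1 <= a_i <= 1 }

Zonotopes are closed under affine maps and Minkowski addition, the two
operations a linear reachability iteration needs, and both reduce to plain
matrix arithmetic.  Initial sets, reachable sets and all bloating sets
(input, parameter-uncertainty, Taylor-remainder, linearization-error) are
zonotopes here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Zonotope",
    "minkowski_sum",
    "affine_map",
    "interval_hull_max",
    "interval_hull",
    "convex_hull_overapprox",
    "reduce_order",
    "contains_point",
]

# Columns with 1-norm below this are dropped: they change the set by less
# than accumulated round-off and only inflate the order.
_PRUNE_TOL = 1e-12

# Absolute feasibility slack for point containment (double-precision
# matrix arithmetic).
_CONTAIN_TOL = 1e-9


@dataclass(frozen=True)
class Zonotope:
    """Centre ``c`` (length n) and generator matrix ``G`` (n x p).

    ``p = 0`` encodes a single point.  Instances are immutable; all
    operations return new zonotopes.
    """

    centre: np.ndarray
    generators: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.centre, dtype=float)).ravel()
        object.__setattr__(self, "centre", c)
        G = self.generators
        if G is None:
            G = np.zeros((c.size, 0))
        G = np.asarray(G, dtype=float)
        if G.ndim == 1:
            G = G.reshape(c.size, -1)
        if G.shape[0] != c.size:
            raise ValueError(
                f"generator rows ({G.shape[0]}) != centre dimension ({c.size})"
            )
        if not (np.all(np.isfinite(c)) and np.all(np.isfinite(G))):
            raise ValueError("non-finite centre or generators")
        object.__setattr__(self, "generators", G)

    # -- basic descriptors -------------------------------------------------
    @property
    def dimension(self) -> int:
        return self.centre.size

    @property
    def n_generators(self) -> int:
        return self.generators.shape[1]

    @property
    def order(self) -> float:
        return self.n_generators / self.dimension

    def is_point(self, tol: float = _PRUNE_TOL) -> bool:
        return self.n_generators == 0 or np.abs(self.generators).sum() < tol

    # -- constructors ------------------------------------------------------
    @staticmethod
    def point(c) -> "Zonotope":
        c = np.atleast_1d(np.asarray(c, dtype=float))
        return Zonotope(c, np.zeros((c.size, 0)))

    @staticmethod
    def from_box(lower, upper) -> "Zonotope":
        """Axis-aligned box with the given per-coordinate bounds."""
        lo = np.atleast_1d(np.asarray(lower, dtype=float))
        hi = np.atleast_1d(np.asarray(upper, dtype=float))
        if np.any(hi < lo):
            raise ValueError("upper < lower in box bounds")
        c = 0.5 * (lo + hi)
        half = 0.5 * (hi - lo)
        return Zonotope(c, np.diag(half)).prune()

    # -- housekeeping ------------------------------------------------------
    def prune(self, tol: float = _PRUNE_TOL) -> "Zonotope":
        """Drop (near-)zero generator columns; the set is unchanged."""
        G = self.generators
        if G.shape[1] == 0:
            return self
        keep = np.abs(G).sum(axis=0) >= tol
        if keep.all():
            return self
        return Zonotope(self.centre, G[:, keep])

    # -- geometry ----------------------------------------------------------
    def interval_hull(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-coordinate (lower, upper) bounds: c -/+ row sums of |G|."""
        r = np.abs(self.generators).sum(axis=1)
        return self.centre - r, self.centre + r

    def support_radius(self) -> np.ndarray:
        """Row sums of |G|: per-coordinate half-width of the interval hull."""
        return np.abs(self.generators).sum(axis=1)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """n random points of the zonotope (rows), a = uniform[-1, 1]^p."""
        a = rng.uniform(-1.0, 1.0, size=(n, self.n_generators))
        return self.centre + a @ self.generators.T

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "centre": self.centre.tolist(),
            "generators": [g.tolist() for g in self.generators.T],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @staticmethod
    def from_dict(d: dict) -> "Zonotope":
        c = np.asarray(d["centre"], dtype=float)
        gens = d.get("generators") or []
        if gens:
            G = np.asarray(gens, dtype=float).T
        else:
            G = np.zeros((c.size, 0))
        return Zonotope(c, G)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Zonotope(n={self.dimension}, p={self.n_generators})"


def _check_same_dim(Z: Zonotope, W: Zonotope) -> None:
    if Z.dimension != W.dimension:
        raise ValueError(
            f"dimension mismatch: {Z.dimension} vs {W.dimension}"
        )


def minkowski_sum(Z: Zonotope, W: Zonotope) -> Zonotope:
    """Exact Minkowski sum: add centres, concatenate generator lists."""
    _check_same_dim(Z, W)
    return Zonotope(
        Z.centre + W.centre, np.hstack([Z.generators, W.generators])
    ).prune()


def affine_map(A, Z: Zonotope, b=None) -> Zonotope:
    """Exact image of Z under x -> A x + b: (A c + b; A G)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.shape[1] != Z.dimension:
        raise ValueError(
            f"matrix columns ({A.shape[1]}) != zonotope dimension ({Z.dimension})"
        )
    c = A @ Z.centre
    if b is not None:
        b = np.asarray(b, dtype=float).ravel()
        if b.size != A.shape[0]:
            raise ValueError("offset length != matrix rows")
        c = c + b
    return Zonotope(c, A @ Z.generators).prune()


def interval_hull_max(Z: Zonotope) -> np.ndarray:
    """Per-coordinate maximum of Z: {c}_i + sum_k |{g_k}_i|.

    Each coordinate's value is attained by some point of Z (set a_k =
    sign of {g_k}_i), though the full vector need not be a member.
    """
    return Z.centre + Z.support_radius()


def interval_hull(Z: Zonotope) -> tuple[np.ndarray, np.ndarray]:
    return Z.interval_hull()


def convex_hull_overapprox(Z1: Zonotope, Z2: Zonotope) -> Zonotope:
    """Zonotope containing conv(Z1 ∪ Z2).

    Zonotopes are not closed under convex hulls; this is the standard
    conservative construction
    ((c1+c2)/2; [(c1-c2)/2, (G1+G2)/2, (G1-G2)/2]) after padding the
    shorter generator list with zero columns.  Every point
    (1+l)/2 x1 + (1-l)/2 x2, l in [-1,1], is realized by the generator
    combination, so the hull is covered.
    """
    _check_same_dim(Z1, Z2)
    p = max(Z1.n_generators, Z2.n_generators)
    n = Z1.dimension

    def pad(G: np.ndarray) -> np.ndarray:
        if G.shape[1] == p:
            return G
        return np.hstack([G, np.zeros((n, p - G.shape[1]))])

    G1, G2 = pad(Z1.generators), pad(Z2.generators)
    c = 0.5 * (Z1.centre + Z2.centre)
    G = np.hstack(
        [
            0.5 * (Z1.centre - Z2.centre).reshape(-1, 1),
            0.5 * (G1 + G2),
            0.5 * (G1 - G2),
        ]
    )
    return Zonotope(c, G).prune()


def reduce_order(Z: Zonotope, max_order: float) -> Zonotope:
    """Conservative order reduction (Girard-style).

    Generators with the smallest ``||g||_1 - ||g||_inf`` score — the ones
    closest to axis-aligned / shortest — are collapsed into their
    axis-aligned interval hull (n box generators); long generators that
    carry the shape are kept.  The output contains the input and has
    order <= max_order.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    Z = Z.prune()
    n, p = Z.dimension, Z.n_generators
    budget = int(np.floor(max_order * n))
    if p <= budget:
        return Z
    # Box m smallest-score generators so that p - m + n <= budget.
    m = p - (budget - n)
    G = Z.generators
    score = np.abs(G).sum(axis=0) - np.abs(G).max(axis=0)
    idx = np.argsort(score, kind="stable")
    boxed, kept = idx[:m], idx[m:]
    half = np.abs(G[:, boxed]).sum(axis=1)
    G_new = np.hstack([G[:, kept], np.diag(half)])
    return Zonotope(Z.centre, G_new).prune()


def contains_point(Z: Zonotope, x, tol: float = _CONTAIN_TOL) -> bool:
    """True iff some a in [-1,1]^p gives c + G a = x (to feasibility slack).

    Decided by a small LP: minimize the infinity-norm residual t subject
    to |G a - (x - c)| <= t, a in [-1,1]^p; membership iff t* <= tol
    (scaled by the magnitude of the data).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != Z.dimension:
        raise ValueError("point dimension mismatch")
    d = x - Z.centre
    scale = max(1.0, np.abs(Z.centre).max(initial=0.0), np.abs(x).max(initial=0.0))
    slack = tol * scale
    G = Z.generators
    p = G.shape[1]
    if p == 0:
        return bool(np.abs(d).max(initial=0.0) <= slack)
    n = Z.dimension
    # variables: [a (p), t (1)]
    cvec = np.zeros(p + 1)
    cvec[-1] = 1.0
    A_ub = np.block(
        [[G, -np.ones((n, 1))], [-G, -np.ones((n, 1))]]
    )
    b_ub = np.concatenate([d, -d])
    bounds = [(-1.0, 1.0)] * p + [(0.0, None)]
    res = linprog(cvec, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - highs is robust on these LPs
        return False
    return bool(res.fun <= slack)
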