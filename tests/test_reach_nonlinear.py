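"""Nonlinear reachability: per-step linearization with error bloating."""

import numpy as np
import pytest
import sympy as sp
from scipy.integrate import solve_ivp

from stochreach.moment_odes import SymbolicMomentSystem, ingest_external_system
from stochreach.reach_linear import ReachConfig, reach_sequence
from stochreach.reach_nonlinear import (
    clamp_nonnegative_projection,
    linearize_at_center,
    nonlinearity_bloat,
    reach_sequence_nonlinear,
    reach_step_nonlinear,
)
from stochreach.zonotope import Zonotope


def scalar_system(expr_str: str) -> SymbolicMomentSystem:
    x = sp.Symbol("x", real=True)
    mu = sp.Symbol("mu", real=True)
    return SymbolicMomentSystem(
        sp.Matrix([sp.sympify(expr_str, locals={"x": x})]), [x], mu, {}, ["x"]
    )


@pytest.fixture(scope="module")
def logistic():
    return scalar_system("x*(1 - x)")


class TestLinearizeAtCenter:
    def test_affine_system_is_exact(self, gene_system):
        A, drift = linearize_at_center(gene_system, np.ones(5), u=1.0)
        A0, b0 = gene_system.affine_system()
        assert np.allclose(A, A0)
        # drift packaged as f(c) - A c = b + B u
        assert np.allclose(drift, b0 + gene_system.input_matrix[:, 0] * 1.0)

    def test_scalar_square_at_three(self):
        sys = scalar_system("x**2")
        A, drift = linearize_at_center(sys, [3.0])
        assert np.isclose(A[0, 0], 6.0)
        assert np.isclose(drift[0], -9.0)

    def test_bistable_jacobian_matches_central_differences(
        self, bistable_lna_system, rng
    ):
        sys = bistable_lna_system
        for _ in range(10):
            c = rng.uniform(0.5, 60.0, sys.n)
            A, _ = linearize_at_center(sys, c)
            h = 1e-6
            for k in range(sys.n):
                dx = np.zeros(sys.n)
                dx[k] = h * max(1.0, c[k])
                col = (sys.f(c + dx) - sys.f(c - dx)) / (2 * dx[k])
                assert np.allclose(A[:, k], col, rtol=1e-4, atol=1e-5)


class TestNonlinearityBloat:
    def test_affine_system_has_zero_bloat(self, gene_system):
        Z = Zonotope(np.ones(5), np.eye(5))
        A, _ = linearize_at_center(gene_system, Z.centre)
        beta, eps = nonlinearity_bloat(gene_system, Z, A, Z.centre, tau=0.01)
        assert beta.is_point() and np.allclose(eps, 0.0)

    def test_scalar_quadratic_exact_remainder(self):
        """For f(x) = x^2 on [c-h, c+h] the Lagrange remainder h^2 is
        exact and the bound recovers it."""
        sys = scalar_system("x**2")
        c, h = 3.0, 0.4
        Z = Zonotope([c], [[h]])
        A = sys.jacobian([c])
        # evaluate the rate-error bound directly (tau only scales the
        # integrated generator, not eps itself)
        _, eps = nonlinearity_bloat(sys, Z, A, [c], tau=1e-12)
        assert np.isclose(eps[0], h**2, rtol=1e-6)

    def test_sampled_errors_below_bound_on_bistable_sets(
        self, bistable_lna_system, rng
    ):
        sys = bistable_lna_system
        for _ in range(20):
            c = np.abs(rng.normal([50, 5, 10, 1, 0.5], [15, 4, 5, 0.5, 0.3]))
            G = rng.normal(0, 1, (5, 3)) * rng.uniform(0.05, 0.5)
            Z = Zonotope(c, G)
            A = sys.jacobian(c)
            _, eps = nonlinearity_bloat(sys, Z, A, c, tau=1e-12)
            fc = sys.f(c)
            for x in Z.sample(300, rng):
                err = np.abs(sys.f(x) - (A @ (x - c) + fc))
                assert np.all(err <= eps + 1e-9)

    def test_sampling_strategy_available_for_ingested_systems(self, rng):
        wrapped = ingest_external_system(lambda x, u: x * (1 - x), n=1)
        Z = Zonotope([0.5], [[0.1]])
        A = wrapped.jacobian([0.5])
        with pytest.raises(ValueError, match="sampling"):
            nonlinearity_bloat(wrapped, Z, A, [0.5], tau=0.01, strategy="corners")
        beta, eps = nonlinearity_bloat(
            wrapped, Z, A, [0.5], tau=0.01, strategy="sampling"
        )
        assert eps[0] > 0

    def test_unknown_strategy_rejected(self, logistic):
        with pytest.raises(ValueError, match="strategy"):
            nonlinearity_bloat(
                logistic, Zonotope([0.5], [[0.1]]), np.eye(1), [0.5], 0.01,
                strategy="nope",
            )


class TestReachStepNonlinear:
    def test_reduces_to_linear_step_on_affine_system(self, gene_system):
        Z = Zonotope(np.array([5.0, 100.0, 5.0, 10.0, 200.0]), np.eye(5) * 0.5)
        cfg = ReachConfig(horizon=1.0, step=0.01, input_center=1.0, interval_sets=False)
        out_nl = reach_step_nonlinear(Z, gene_system, cfg)
        seq_lin = reach_sequence(gene_system, Z, cfg)
        out_lin = seq_lin.sets[1]
        assert np.allclose(out_nl.centre, out_lin.centre, atol=1e-9)
        lo1, hi1 = out_nl.interval_hull()
        lo2, hi2 = out_lin.interval_hull()
        assert np.allclose(lo1, lo2, atol=1e-9) and np.allclose(hi1, hi2, atol=1e-9)

    def test_logistic_flow_containment(self, logistic, rng):
        cfg = ReachConfig(horizon=3.0, step=0.01, interval_sets=False)
        I = Zonotope.from_box([0.1], [0.2])
        seq = reach_sequence_nonlinear(logistic, I, cfg)
        check = range(0, len(seq.times), 30)
        for x0 in rng.uniform(0.1, 0.2, 50):
            sol = solve_ivp(
                lambda t, x: x * (1 - x), (0, 3.0), [x0],
                rtol=1e-11, atol=1e-13, t_eval=seq.times[list(check)],
            )
            for j, k in enumerate(check):
                lo, hi = seq.sets[k].interval_hull()
                assert lo[0] - 1e-8 <= sol.y[0, j] <= hi[0] + 1e-8


class TestReachSequenceNonlinear:
    def test_monostable_runs_converge_to_their_fixed_points(
        self, bistable_mean_system
    ):
        """Initial Nanog windows inside a single basin converge to that
        basin's stable state with no negative excursion."""
        cfg = ReachConfig(horizon=15.0, step=0.01, interval_sets=False,
                          nonnegative=["mean_N"])
        results = {}
        for label, (lo0, hi0) in {"low": (0.3, 0.5), "high": (1.5, 2.5)}.items():
            I = Zonotope.from_box([60.0, lo0], [60.0, hi0])
            seq = reach_sequence_nonlinear(bistable_mean_system, I, cfg)
            _, flags = clamp_nonnegative_projection(seq, ["mean_N"])
            assert not flags["mean_N"]
            lo, hi = seq.sets[-1].interval_hull()
            results[label] = 0.5 * (lo[1] + hi[1])
            assert hi[1] - lo[1] < 0.01  # converged to a narrow window
        assert results["low"] < 0.2
        assert 12.0 < results["high"] < 15.0

    def test_fixed_and_adaptive_stepping_agree_on_logistic(self, logistic):
        I = Zonotope.from_box([0.1], [0.2])
        fixed = reach_sequence_nonlinear(
            logistic, I, ReachConfig(horizon=3.0, step=0.005, interval_sets=False)
        )
        adaptive = reach_sequence_nonlinear(
            logistic, I,
            ReachConfig(horizon=3.0, step=0.005, interval_sets=False, adaptive=True),
        )
        lo_f, hi_f = fixed.sets[-1].interval_hull()
        lo_a, hi_a = adaptive.sets[-1].interval_hull()
        assert abs(lo_f[0] - lo_a[0]) < 0.01 * max(1.0, abs(lo_f[0]))
        assert abs(hi_f[0] - hi_a[0]) < 0.01 * max(1.0, abs(hi_f[0]))

    def test_divergent_centre_reports_failing_time(self):
        exploding = scalar_system("x**2")
        I = Zonotope.point([5.0])
        cfg = ReachConfig(horizon=5.0, step=0.01, interval_sets=False)
        with pytest.raises(RuntimeError, match="diverged|non-finite"):
            reach_sequence_nonlinear(exploding, I, cfg)

    def test_interval_sets_cover_between_grid_solutions(self, logistic, rng):
        cfg = ReachConfig(horizon=1.0, step=0.05)
        I = Zonotope.from_box([0.1], [0.2])
        seq = reach_sequence_nonlinear(logistic, I, cfg)
        for x0 in rng.uniform(0.1, 0.2, 10):
            sol = solve_ivp(
                lambda t, x: x * (1 - x), (0, 1.0), [x0],
                rtol=1e-10, atol=1e-12, dense_output=True,
            )
            for i in range(len(seq.interval_sets)):
                for s in np.linspace(seq.times[i], seq.times[i + 1], 7):
                    lo, hi = seq.interval_sets[i].interval_hull()
                    assert lo[0] - 1e-8 <= sol.sol(s)[0] <= hi[0] + 1e-8


class TestClampNonnegative:
    def _toy_sequence(self, lows):
        from stochreach.reach_linear import ReachSequence

        sets = [Zonotope.from_box([lo], [5.0]) for lo in lows]
        return ReachSequence(
            np.arange(len(sets), dtype=float), sets, ["mean_X"]
        )

    def test_all_positive_unchanged(self):
        seq = self._toy_sequence([0.5, 1.0])
        df, flags = clamp_nonnegative_projection(seq, ["mean_X"])
        assert not flags["mean_X"]
        assert (df["lower"] >= 0.5).all()

    def test_negative_lower_bound_clamped_and_flagged(self):
        seq = self._toy_sequence([-1.0, 2.0])
        df, flags = clamp_nonnegative_projection(seq, ["mean_X"])
        assert flags["mean_X"]
        assert df.loc[df["time"] == 0.0, "lower"].item() == 0.0
        assert df.loc[df["time"] == 0.0, "upper"].item() == 5.0

    def test_original_sets_untouched(self):
        seq = self._toy_sequence([-1.0])
        clamp_nonnegative_projection(seq, ["mean_X"])
        lo, _ = seq.sets[0].interval_hull()
        assert lo[0] == -1.0
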