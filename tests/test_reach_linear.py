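"""Linear reachability: one-step operators and full sequences."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from stochreach.moment_odes import ingest_external_system
from stochreach.reach_linear import (
    ParameterUncertainty,
    ReachConfig,
    initial_interval_bloat,
    input_bloat,
    param_bloat,
    psi,
    reach_sequence,
    reach_step,
)
from stochreach.zonotope import Zonotope, contains_point

GENE_STATIONARY = np.array([20.0, 2000.0, 20.0, 1000.0 / 3.0, 106000.0 / 3.0])


class TestPsi:
    def test_scalar_closed_form(self):
        P, rem = psi(np.array([[-1.0]]), np.log(2.0))
        assert rem is None
        assert np.isclose(P[0, 0], 0.5)  # (-1)^{-1}(e^{-ln 2} - 1)

    def test_singular_matrix_taylor_limit(self):
        A = np.zeros((2, 2))
        t = 0.3
        P, rem = psi(A, t, order=4)
        assert np.allclose(P, t * np.eye(2))
        assert rem is not None and np.allclose(rem, 0.0)

    def test_remainder_shrinks_with_order(self):
        A = np.array([[0.0, 1.0], [0.0, 0.0]])  # nilpotent, singular
        rems = []
        for order in (2, 4, 6):
            _, rem = psi(A, 0.5, order=order)
            rems.append(rem.max())
        assert rems[0] >= rems[1] >= rems[2]

    def test_matches_quadrature_for_random_stable_system(self, rng):
        """psi(A, t) B u equals the forced-response integral
        int_0^t e^{As} B u ds (high-accuracy quadrature oracle)."""
        for _ in range(5):
            A = rng.normal(0, 1, (3, 3)) - 3 * np.eye(3)
            B = rng.normal(0, 1, (3, 1))
            u, t = 1.7, 0.8
            P, _ = psi(A, t)
            s_grid = np.linspace(0, t, 4001)
            vals = np.stack([expm(A * s) @ B[:, 0] * u for s in s_grid])
            integral = np.trapezoid(vals, s_grid, axis=0)
            assert np.allclose(P @ B[:, 0] * u, integral, rtol=1e-6, atol=1e-8)

    def test_invalid_time_rejected(self):
        with pytest.raises(ValueError):
            psi(np.eye(2), 0.0)


class TestInputBloat:
    def test_no_uncertainty_is_pure_drift(self):
        A = -np.eye(2)
        B = np.array([[1.0], [0.0]])
        out = input_bloat(A, 0.1, B, u_c=2.0, u_d=0.0)
        P, _ = psi(A, 0.1)
        assert out.n_generators == 0
        assert np.allclose(out.centre, P @ B[:, 0] * 2.0)

    def test_unit_interval_input_encoding(self):
        # mu in [0, 1] encoded as centre 1/2, halfwidth 1/2: the drift and
        # the uncertainty generator coincide
        A = -2 * np.eye(1)
        B = np.array([[3.0]])
        out = input_bloat(A, 0.05, B, u_c=0.5, u_d=0.5)
        assert np.allclose(out.centre, out.generators[:, 0])

    def test_one_step_forced_responses_contained(self, rng):
        """Exact solutions x(tau) under 50 constant inputs drawn from the
        admissible interval stay inside e^{A tau} x0 + beta_mu."""
        A = np.array([[-1.0, 0.4], [0.2, -2.0]])
        B = np.array([[1.0], [0.5]])
        tau, u_c, u_d = 0.2, 0.5, 0.5
        x0 = np.array([1.0, -1.0])
        bloat = input_bloat(A, tau, B, u_c, u_d)
        step = Zonotope(expm(A * tau) @ x0, np.zeros((2, 0)))
        R = reach_step(step, np.eye(2), [bloat])
        for u in rng.uniform(u_c - u_d, u_c + u_d, 50):
            sol = solve_ivp(
                lambda t, x: A @ x + B[:, 0] * u,
                (0, tau),
                x0,
                rtol=1e-11,
                atol=1e-13,
            )
            assert contains_point(R, sol.y[:, -1], tol=1e-7)

    def test_negative_halfwidth_rejected(self):
        with pytest.raises(ValueError):
            input_bloat(-np.eye(1), 0.1, np.ones((1, 1)), 0.0, -0.1)


class TestParamBloat:
    def test_zero_delta_short_circuits(self):
        A = -np.eye(2)
        out = param_bloat(A, A, np.eye(2), Zonotope.point([1.0, 2.0]), expm(A * 0.1))
        assert out.is_point() and np.allclose(out.centre, 0.0)

    def test_scalar_decay_closed_form(self):
        """xdot = -k x, k = 1 +/- 0.1, current set the point {2}:
        D_unc = 0.1, |x|max = 2, half-width = |psi(-1, tau)| * 0.2."""
        tau = 0.1
        A = np.array([[-1.0]])
        A_pert = np.array([[-1.1]])
        P, _ = psi(A, tau)
        out = param_bloat(A, A_pert, P, Zonotope.point([2.0]), expm(A * tau))
        assert np.isclose(out.support_radius()[0], abs(P[0, 0]) * 0.2)

    def test_gene_k4_uncertainty_covers_sampled_rates(self, gene_network, rng):
        """Trajectories of the moment system under 20 sampled protein
        degradation rates within 5% of nominal stay inside the bloated
        reach sets."""
        from stochreach.moment_odes import lna_derive

        cfg = ReachConfig(
            horizon=2.0,
            step=0.01,
            input_center=1.0,
            input_halfwidth=0.0,
            uncertainties=[ParameterUncertainty("k4", 1.0, 0.05)],
            interval_sets=False,
        )
        sys = lna_derive(gene_network)
        seq = reach_sequence(sys, Zonotope.point(np.zeros(5)), cfg)
        check_idx = range(0, len(seq.times), 20)
        for k4 in rng.uniform(0.95, 1.05, 20):
            pert = lna_derive(
                type(gene_network)(
                    gene_network.species,
                    gene_network.stoichiometry,
                    gene_network.propensities,
                    {**gene_network.parameters, "k4": float(k4)},
                )
            )
            sol = solve_ivp(
                lambda t, x: pert.f(x, 1.0),
                (0, 2.0),
                np.zeros(5),
                rtol=1e-10,
                atol=1e-12,
                t_eval=seq.times[list(check_idx)],
            )
            for j, k in enumerate(check_idx):
                lo, hi = seq.sets[k].interval_hull()
                x = sol.y[:, j]
                assert np.all(x >= lo - 1e-7) and np.all(x <= hi + 1e-7)


class TestReachStep:
    def test_frozen_dynamics_identity(self, rng):
        Z = Zonotope(rng.normal(0, 1, 2), rng.normal(0, 1, (2, 3)))
        out = reach_step(Z, np.eye(2))
        assert np.allclose(out.centre, Z.centre)
        assert np.allclose(out.generators, Z.generators)

    def test_scalar_decay_maps_interval_endpoints(self):
        tau = 0.25
        Z = Zonotope.from_box([1.0], [2.0])
        out = reach_step(Z, expm(np.array([[-1.0]]) * tau))
        lo, hi = out.interval_hull()
        assert np.isclose(lo[0], np.exp(-tau) * 1.0)
        assert np.isclose(hi[0], np.exp(-tau) * 2.0)

    def test_autonomous_centre_follows_matrix_exponential(self, rng):
        A = rng.normal(0, 1, (2, 2)) - 2 * np.eye(2)
        x0 = rng.normal(0, 1, 2)
        sys = ingest_external_system(
            lambda x, u: A @ x, n=2, jac=lambda x, u: A, is_affine=True
        )
        cfg = ReachConfig(horizon=1.0, step=0.02, interval_sets=False)
        seq = reach_sequence(sys, Zonotope.point(x0), cfg)
        for t, Z in zip(seq.times, seq.sets):
            assert np.allclose(Z.centre, expm(A * t) @ x0, atol=1e-10)
            assert Z.n_generators == 0  # zero generator growth


class TestInitialIntervalBloat:
    def test_static_system_returns_initial_set(self):
        I = Zonotope.from_box([0.0, 1.0], [1.0, 2.0])
        out = initial_interval_bloat(I, np.zeros((2, 2)), 0.1, mu_bound=0.0)
        assert np.allclose(out.interval_hull(), I.interval_hull())

    def test_scalar_decay_dense_samples_contained(self):
        A = np.array([[-1.0]])
        tau = 0.2
        I = Zonotope.point([1.0])
        out = initial_interval_bloat(I, A, tau, mu_bound=0.0)
        for s in np.linspace(0, tau, 200):
            assert contains_point(out, [np.exp(-s)], tol=1e-8)

    def test_propagated_interval_covers_next_window(self):
        A = np.array([[-1.0]])
        tau = 0.2
        I = Zonotope.point([1.0])
        R0 = initial_interval_bloat(I, A, tau, mu_bound=0.0)
        R1 = reach_step(R0, expm(A * tau))
        for s in np.linspace(tau, 2 * tau, 200):
            assert contains_point(R1, [np.exp(-s)], tol=1e-8)


class TestReachSequence:
    def test_gene_expression_reaches_printed_stationary_means(self, gene_system):
        cfg = ReachConfig(
            horizon=25.0, step=0.01, input_center=1.0, interval_sets=False
        )
        seq = reach_sequence(gene_system, Zonotope.point(np.zeros(5)), cfg)
        final = seq.sets[-1].centre
        assert np.allclose(final[:2], [20.0, 2000.0], rtol=1e-8)
        assert np.allclose(final, GENE_STATIONARY, rtol=1e-8)

    def test_zero_input_from_origin_stays_at_origin(self, gene_system):
        cfg = ReachConfig(horizon=1.0, step=0.01, interval_sets=False)
        seq = reach_sequence(gene_system, Zonotope.point(np.zeros(5)), cfg)
        assert all(Z.is_point() and np.allclose(Z.centre, 0) for Z in seq.sets)

    def test_nonaffine_system_directed_to_nonlinear_engine(
        self, bistable_mean_system
    ):
        with pytest.raises(ValueError, match="nonlinear"):
            reach_sequence(
                bistable_mean_system,
                Zonotope.point([60.0, 0.5]),
                ReachConfig(horizon=1.0, step=0.1),
            )

    def test_interval_sets_contain_their_endpoints(self, gene_system, rng):
        cfg = ReachConfig(
            horizon=0.5, step=0.05, input_center=0.5, input_halfwidth=0.5
        )
        seq = reach_sequence(gene_system, Zonotope.point(np.zeros(5)), cfg)
        for i, R_int in enumerate(seq.interval_sets):
            for Z in (seq.sets[i], seq.sets[i + 1]):
                for x in Z.sample(10, rng):
                    assert contains_point(R_int, x, tol=1e-6)

    def test_monotone_in_input_uncertainty(self, gene_system):
        """Widening the admissible input interval never shrinks any
        coordinate's reachable interval at any time."""
        base = ReachConfig(
            horizon=2.0, step=0.01, input_center=0.5, input_halfwidth=0.2,
            interval_sets=False,
        )
        wide = ReachConfig(
            horizon=2.0, step=0.01, input_center=0.5, input_halfwidth=0.5,
            interval_sets=False,
        )
        I = Zonotope.point(np.zeros(5))
        s1 = reach_sequence(gene_system, I, base)
        s2 = reach_sequence(gene_system, I, wide)
        for Z1, Z2 in zip(s1.sets, s2.sets):
            lo1, hi1 = Z1.interval_hull()
            lo2, hi2 = Z2.interval_hull()
            assert np.all(lo2 <= lo1 + 1e-9) and np.all(hi2 >= hi1 - 1e-9)

    def test_monotone_in_parameter_uncertainty(self, gene_system):
        cfgs = [
            ReachConfig(
                horizon=2.0, step=0.01, input_center=1.0,
                uncertainties=[ParameterUncertainty("k4", 1.0, d)] if d else [],
                interval_sets=False,
            )
            for d in (0.0, 0.05)
        ]
        I = Zonotope.point(np.zeros(5))
        s1, s2 = (reach_sequence(gene_system, I, c) for c in cfgs)
        for Z1, Z2 in zip(s1.sets, s2.sets):
            lo1, hi1 = Z1.interval_hull()
            lo2, hi2 = Z2.interval_hull()
            assert np.all(lo2 <= lo1 + 1e-9) and np.all(hi2 >= hi1 - 1e-9)

    def test_stationary_covariance_lyapunov_residual(self, gene_network, gene_system):
        """Converged covariances satisfy the stationary fluctuation
        balance SD Sigma + Sigma (SD)^T + S diag{F} S^T = 0."""
        from stochreach.moment_odes import unpack_state

        cfg = ReachConfig(horizon=25.0, step=0.01, input_center=1.0, interval_sets=False)
        seq = reach_sequence(gene_system, Zonotope.point(np.zeros(5)), cfg)
        phi, Sig = unpack_state(seq.sets[-1].centre, 2)
        S = gene_network.stoichiometry
        k1, k2, k3, k4 = 100.0, 5.0, 100.0, 1.0
        F = np.array([k1 * 1.0, k2 * phi[0], k3 * phi[0], k4 * phi[1]])
        D = np.array([[0, 0], [k2, 0], [k3, 0], [0, k4]])
        SD = S @ D
        resid = SD @ Sig + Sig @ SD.T + S @ np.diag(F) @ S.T
        assert np.abs(resid).max() / np.abs(Sig).max() < 1e-6


class TestReachSequenceOutput:
    def test_csv_and_jsonl_round_trip(self, gene_system, tmp_path):
        import json

        import pandas as pd

        cfg = ReachConfig(horizon=0.2, step=0.05, input_center=1.0)
        seq = reach_sequence(gene_system, Zonotope.point(np.zeros(5)), cfg)
        seq.write_csv(tmp_path / "hulls.csv")
        seq.write_jsonl(tmp_path / "sets.jsonl")
        df = pd.read_csv(tmp_path / "hulls.csv")
        assert set(df.columns) == {"time", "var", "lower", "upper"}
        assert len(df) == len(seq.times) * 5
        lines = [json.loads(l) for l in (tmp_path / "sets.jsonl").read_text().splitlines()]
        kinds = {l["kind"] for l in lines}
        assert kinds == {"point", "interval"}
        Z = Zonotope.from_dict(lines[0])
        assert np.allclose(Z.centre, seq.sets[0].centre)
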