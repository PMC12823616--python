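"""Assembly, Newton solve, convergence study and parameter sweeps."""

import numpy as np
import pytest

from fracsir.collocation import (SolverConfig, SolverError, assemble,
                                 convergence_study, solve, sweep)
from fracsir.delay import HistorySet
from fracsir.fixtures import make_manufactured, make_ml_decay
from fracsir.model import SIRParameters, default_scenario


def _constant_histories(S0, I0, R0, tau):
    mk = lambda v: (lambda t: v * np.ones_like(np.asarray(t, dtype=float)))
    return HistorySet(mk(S0), mk(I0), mk(R0), tau=tau)


class TestAssemble:
    def test_square_system_size(self, base_params):
        _, hist = default_scenario("as_text")
        prob = assemble(base_params, hist, SolverConfig(J=6))
        assert prob.n_b == 2**6 + 1
        assert prob.n_unknowns == 3 * prob.n_b
        assert prob.Psi.shape == (prob.n_b, prob.n_b)
        assert np.isfinite(prob.diagnostics["condition_Psi"])

    def test_tau_must_be_inside_horizon(self):
        with pytest.raises(ValueError):
            p = SIRParameters(beta=0.0, gamma=0.1, delta=0.0, alpha=0.9,
                              tau=12.0, N=700.0, T=10.0)

    def test_small_basis_rejected(self, base_params):
        _, hist = default_scenario("as_text")
        with pytest.raises(ValueError, match="at least 8"):
            assemble(base_params, hist, SolverConfig(J=2))

    def test_nodes_avoid_zero(self, base_params):
        _, hist = default_scenario("as_text")
        prob = assemble(base_params, hist, SolverConfig(J=4))
        assert prob.nodes[0] > 0.0
        assert prob.nodes[-1] < base_params.T

    @pytest.mark.parametrize("alpha,degree", [(1.0, 1), (0.6, 3), (0.3, 2)])
    def test_manufactured_exact_residual(self, alpha, degree):
        p = SIRParameters(beta=5e-4, gamma=0.1, delta=0.05, alpha=alpha,
                          tau=2.0, N=700.0, T=10.0)
        mp = make_manufactured(degree, p)
        prob = assemble(mp.params, mp.histories, SolverConfig(J=5),
                        forcing=mp.forcing)
        res = prob.residual_from_exact(mp.exact, mp.exact_caputo)
        assert np.max(np.abs(res)) < 1e-8

    def test_zero_dynamics_solved_by_constants(self):
        p = SIRParameters(beta=0.0, gamma=0.0, delta=0.0, alpha=0.8,
                          tau=1.0, N=700.0, T=5.0)
        hist = _constant_histories(500.0, 80.0, 120.0, 1.0)
        cfg = SolverConfig(J=4)
        prob = assemble(p, hist, cfg)
        assert np.max(np.abs(prob.residual(np.zeros((3, prob.n_b))))) < 1e-12
        sol = solve(prob, cfg)
        assert np.max(np.abs(sol.S - 500.0)) < 1e-9
        assert sol.iterations <= 1


class TestJacobian:
    def test_analytic_matches_finite_differences(self, base_params):
        _, hist = default_scenario("as_text")
        cfg = SolverConfig(J=3)  # small so the FD sweep stays cheap
        p = base_params.with_(alpha=0.7)
        prob = assemble(p, hist, SolverConfig(J=4))
        rng = np.random.default_rng(7)
        A = 0.1 * rng.normal(size=(3, prob.n_b))
        J_an = prob.jacobian(A)
        J_fd = prob.fd_jacobian(A, eps=1e-7)
        scale = np.max(np.abs(J_an))
        assert np.max(np.abs(J_an - J_fd)) / scale < 1e-6


class TestSolve:
    def test_mittag_leffler_relaxation(self):
        ml = make_ml_decay(0.7, gamma=0.1, I0=70.0, T=10.0)
        cfg = SolverConfig(J=6)
        sol = solve(assemble(ml.params, ml.histories, cfg), cfg)
        t5 = np.argmin(np.abs(sol.times - 5.0))
        want = ml.exact[1](np.array([5.0])).item()
        assert abs(sol.I[t5] - want) / want < 1e-3

    def test_initial_values_enforced_exactly(self):
        params, hist = default_scenario("as_text", alpha=0.85)
        cfg = SolverConfig(J=5)
        sol = solve(assemble(params, hist, cfg), cfg)
        assert sol.times[0] == 0.0
        assert sol.S[0] == 620.0
        assert sol.I[0] == 10.0
        assert sol.R[0] == 70.0

    @pytest.mark.parametrize("degree,alpha", [(0, 0.5), (1, 1.0)])
    def test_manufactured_recovery(self, degree, alpha):
        p = SIRParameters(beta=5e-4, gamma=0.1, delta=0.05, alpha=alpha,
                          tau=2.0, N=700.0, T=10.0)
        mp = make_manufactured(degree, p)
        cfg = SolverConfig(J=5)
        sol = solve(assemble(mp.params, mp.histories, cfg, forcing=mp.forcing),
                    cfg)
        err = max(np.max(np.abs(sol.S - mp.exact[0](sol.times))),
                  np.max(np.abs(sol.I - mp.exact[1](sol.times))),
                  np.max(np.abs(sol.R - mp.exact[2](sol.times))))
        assert err < 1e-6

    def test_deterministic_bit_identical(self):
        params, hist = default_scenario("as_text", alpha=0.8)
        cfg = SolverConfig(J=4)
        a = solve(assemble(params, hist, cfg), cfg)
        b = solve(assemble(params, hist, cfg), cfg)
        assert np.array_equal(a.S, b.S) and np.array_equal(a.I, b.I) \
            and np.array_equal(a.R, b.R)

    def test_fixed_point_method_agrees_with_newton(self):
        ml = make_ml_decay(0.9, gamma=0.05, T=5.0)
        cfg_n = SolverConfig(J=4, method="newton")
        cfg_f = SolverConfig(J=4, method="fixed_point", max_iter=200)
        a = solve(assemble(ml.params, ml.histories, cfg_n), cfg_n)
        b = solve(assemble(ml.params, ml.histories, cfg_f), cfg_f)
        assert np.max(np.abs(a.I - b.I)) < 1e-7

    def test_nonconvergence_raises_with_history(self):
        params, hist = default_scenario("as_text", alpha=0.8)
        cfg = SolverConfig(J=4, max_iter=1, residual_tol=1e-14)
        with pytest.raises(SolverError) as exc:
            solve(assemble(params, hist, cfg), cfg)
        assert len(exc.value.history) >= 1

    def test_sample_outside_horizon_rejected(self):
        params, hist = default_scenario("as_text", alpha=0.8)
        cfg = SolverConfig(J=4)
        sol = solve(assemble(params, hist, cfg), cfg)
        with pytest.raises(ValueError):
            sol.sample([11.0])


class TestConvergenceStudy:
    def test_manufactured_in_span_hits_floor(self):
        p = SIRParameters(beta=5e-4, gamma=0.1, delta=0.05, alpha=1.0,
                          tau=2.0, N=700.0, T=10.0)
        mp = make_manufactured(1, p)
        records, _ = convergence_study(mp, [4, 5], n_fine=401)
        assert all(r["l2_error"] < 1e-8 for r in records)

    def test_ml_fixture_errors_decrease(self):
        records, order = convergence_study(make_ml_decay(0.5, T=5.0), [4, 5, 6],
                                           n_fine=401)
        errs = [r["l2_error"] for r in records]
        assert errs[0] > errs[1] > errs[2]
        assert order > 0.0


class TestSweep:
    def test_singleton_equals_single_solve(self, base_params):
        _, hist = default_scenario("as_text")
        cfg = SolverConfig(J=4)
        [(v, sol)] = sweep(base_params, hist, "alpha", [0.9], cfg)
        direct = solve(assemble(base_params, hist, cfg), cfg)
        assert v == 0.9
        assert np.array_equal(sol.I, direct.I)

    def test_alpha_sweep_conserves_population(self, base_params):
        _, hist = default_scenario("as_text")
        cfg = SolverConfig(J=4)
        results = sweep(base_params, hist, "alpha", [0.3, 0.5, 0.7, 0.9, 1.0], cfg)
        assert len(results) == 5
        for _, sol in results:
            assert not isinstance(sol, Exception)
            assert sol.conservation <= 1e-6

    def test_infection_peak_monotone_in_beta(self):
        # classical limit, cross-checked against the RK4 oracle
        from fracsir.reference import OracleConfig, rk4_dde

        # long-horizon outbreaks need J = 7: at J = 6 the sharp peak is
        # underresolved and Newton can land on a spurious discrete root
        params, hist = default_scenario("as_text", alpha=1.0, T=30.0)
        cfg = SolverConfig(J=7)
        betas = [4e-4, 8e-4, 1.6e-3]
        results = sweep(params, hist, "beta", betas, cfg)
        peaks = [np.max(sol.I) for _, sol in results]
        assert peaks[0] <= peaks[1] <= peaks[2]
        rk_peaks = [np.max(rk4_dde(params.with_(beta=b), hist,
                                   OracleConfig(h=2e-3)).I) for b in betas]
        for p_hybrid, p_rk in zip(peaks, rk_peaks):
            assert abs(p_hybrid - p_rk) / p_rk < 1e-2

    def test_unknown_parameter_rejected(self, base_params):
        _, hist = default_scenario("as_text")
        with pytest.raises(ValueError):
            sweep(base_params, hist, "N", [600.0])
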