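"""FBA solving, basis bookkeeping, degeneracy, and forward-basis selection,
checked against the fully worked dynamic LP and brute-force oracles."""

import numpy as np
import pytest

from oracles import (
    brute_force_lp_max,
    forward_rates_of_basis,
    make_degenerate_lp,
)

from dfbasis.fixtures import make_example1, make_toy_model
from dfbasis.lp import (
    BasisState,
    build_standard_form,
    check_forward_feasibility,
    compute_basic_solution,
    enumerate_bases_of_solution,
    find_active_constraints,
    select_forward_basis,
    solve_fba,
)
from dfbasis.model import BoundSpec, ConstraintSystem, build_constraint_system


def _native_system(A, c0, cdot):
    A = np.asarray(A, dtype=float)
    return ConstraintSystem(
        A=A,
        c_of=lambda y, t: np.asarray(c0) + t * np.asarray(cdot),
        n=A.shape[0],
        Gamma_dagger=np.zeros((0, A.shape[1])),
        row_labels=[f"row{i}" for i in range(A.shape[0])],
        dc_of=lambda y, t, ydot: np.asarray(cdot, dtype=float),
        nonneg=True,
    )


class TestSolveFBA:
    def test_worked_example_unique_solution(self, example1):
        system, gamma = example1
        sol, basis = solve_fba(system, gamma, None, 0.0)
        np.testing.assert_allclose(sol.w, [10, 10, 0, 0, 0], atol=1e-9)
        assert sol.objective == pytest.approx(20.0)
        assert len(basis.index_set) == 3

    def test_zero_objective_gives_zero_value(self, example1):
        system, _ = example1
        sol, _ = solve_fba(system, np.zeros(2), None, 0.0)
        assert sol.objective == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_vertex_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(2, 4))
        n = int(rng.integers(3, 6))
        A = rng.normal(size=(n, d))
        x0 = rng.uniform(0.2, 1.5, size=d)
        c0 = A @ x0 + rng.uniform(0.1, 1.0, size=n)
        # bound every direction so vertices exist
        A = np.vstack([A, np.eye(d)])
        c0 = np.concatenate([c0, np.full(d, 5.0)])
        gamma = rng.normal(size=d)
        system = _native_system(A, c0, np.zeros(n + d))
        sol, _ = solve_fba(system, gamma, None, 0.0)
        assert sol.objective == pytest.approx(
            brute_force_lp_max(A, c0, gamma, nonneg=True), abs=1e-7)

    def test_gem_solution_satisfies_steady_state(self, toy_static):
        model, bounds, notes = toy_static
        system = build_constraint_system(model, bounds)
        sol, _ = solve_fba(system, model.gamma, np.array([10.0, 10.0]), 0.0)
        np.testing.assert_allclose(model.Gamma_dagger @ sol.phi, 0.0, atol=1e-9)
        assert sol.objective == pytest.approx(notes["mu"])
        np.testing.assert_allclose(sol.psi, model.Gamma_star @ sol.phi)


class TestBasicSolutions:
    def test_tracked_solutions_of_each_worked_basis(self, example1):
        system, gamma = example1
        std = build_standard_form(system, gamma)
        t = 6.0
        rhs = std.rhs(None, t)
        # basis {v1, v2, s2}: w = (10, 10 - t/2, 0, t/2, 0)
        w2 = compute_basic_solution(BasisState.from_indices(std, (0, 1, 3)), rhs)
        np.testing.assert_allclose(w2, [10, 10 - t / 2, 0, t / 2, 0], atol=1e-9)
        # basis {v1, v2, s1}: w = (10 - t, 10, t, 0, 0)
        w1 = compute_basic_solution(BasisState.from_indices(std, (0, 1, 2)), rhs)
        np.testing.assert_allclose(w1, [10 - t, 10, t, 0, 0], atol=1e-9)
        # the first tracks the optimum, the second is sub-optimal for t > 0
        assert std.gamma_tilde @ w2 > std.gamma_tilde @ w1

    def test_zero_rhs_gives_zero(self, example1):
        system, gamma = example1
        std = build_standard_form(system, gamma)
        w = compute_basic_solution(BasisState.from_indices(std, (0, 1, 3)), np.zeros(3))
        np.testing.assert_allclose(w, 0.0)

    def test_exactly_three_bases_for_worked_optimum(self, example1):
        system, gamma = example1
        sol, _ = solve_fba(system, gamma, None, 0.0)
        std = build_standard_form(system, gamma)
        bases = enumerate_bases_of_solution(std, sol.w, std.rhs(None, 0.0))
        assert len(bases) == 3
        # every basis keeps both structural variables (they are nonzero)
        assert all({0, 1} <= set(b) for b in bases)

    def test_degeneracy_iff_zero_basic_variable(self):
        # non-degenerate instance: unique basis; degenerate worked example: three
        system, gamma = make_example1()
        sol, _ = solve_fba(system, gamma, None, 0.0)
        std = build_standard_form(system, gamma)
        assert min(abs(sol.w[list(range(3))]).min() for _ in [0]) is not None
        bases = enumerate_bases_of_solution(std, sol.w, std.rhs(None, 0.0))
        degenerate = len(bases) > 1
        basic_zero_exists = any(
            np.any(np.abs(compute_basic_solution(BasisState.from_indices(std, b),
                                                 std.rhs(None, 0.0))[list(b)]) <= 1e-9)
            for b in bases)
        assert degenerate == basic_zero_exists


class TestActiveSet:
    def test_worked_example_at_switch_time(self, example1):
        system, _ = example1
        act = find_active_constraints(np.array([10.0, 0.0]), system, None, 20.0)
        # v1 <= 10 tight, v1 + 2 v2 <= 10 tight, v2 at its nonnegativity bound
        assert act.rows == [0, 2, 4]
        assert np.linalg.matrix_rank(act.matrix) == 2

    def test_interior_point_keeps_only_steady_state_rows(self, toy_static):
        model, bounds, _ = toy_static
        system = build_constraint_system(model, bounds)
        phi = np.full(model.d, 1e-3) * 0  # zero flux is interior except lower bounds
        phi = np.array([0.01, 0.01])
        act = find_active_constraints(phi, system, np.array([10.0, 10.0]), 0.0,
                                      require_vertex=False)
        assert act.rows == list(range(system.n, system.n + system.m_eq))

    @pytest.mark.parametrize("seed", range(10))
    def test_vertex_solutions_have_rank_d(self, seed):
        A, c0, cdot, gamma, _ = make_degenerate_lp(seed)
        system = _native_system(A, c0, cdot)
        sol, _ = solve_fba(system, gamma, None, 0.0)
        act = find_active_constraints(sol.phi, system, None, 0.0)
        assert np.linalg.matrix_rank(act.matrix, tol=1e-8) == system.d


class TestForwardBasisSelection:
    def test_tracks_shrinking_mixed_bound(self, example1):
        """dc/dt = (0,0,-1): the basis holding v1 and the mixed row is chosen."""
        system, gamma = example1
        sol, _ = solve_fba(system, gamma, None, 0.0)
        act = find_active_constraints(sol.phi, system, None, 0.0)
        fb = select_forward_basis(sol, act, [0.0, 0.0, -1.0], gamma)
        assert fb.row_subset == [0, 2]
        for t in (1.0, 10.0, 19.0):
            np.testing.assert_allclose(fb.phi_at(None, t), [10.0, 10.0 - t / 2],
                                       atol=1e-9)

    def test_counterfactual_bound_direction(self, example1):
        """dc/dt = (-1,-1,0): the basis holding both box rows is chosen instead."""
        system, gamma = example1
        sol, _ = solve_fba(system, gamma, None, 0.0)
        act = find_active_constraints(sol.phi, system, None, 0.0)
        fb = select_forward_basis(sol, act, [-1.0, -1.0, 0.0], gamma)
        assert fb.row_subset == [0, 1]
        np.testing.assert_allclose(fb.phi_dot, [-1.0, -1.0], atol=1e-9)

    @pytest.mark.parametrize("seed", range(25))
    def test_maximizes_over_enumerated_bases(self, seed):
        """Selected forward rate equals the brute-force best over all bases."""
        A, c0, cdot, gamma, _ = make_degenerate_lp(seed)
        system = _native_system(A, c0, cdot)
        sol, _ = solve_fba(system, gamma, None, 0.0)
        std = build_standard_form(system, gamma)
        bases = enumerate_bases_of_solution(std, sol.w, std.rhs(None, 0.0))
        assert len(bases) >= 2, "instance not degenerate"
        rhs_dot = np.asarray(cdot)
        best = -np.inf
        for b in bases:
            phi_dot, ok = forward_rates_of_basis(std.A_full, b, rhs_dot, system.d, sol.w)
            if ok:
                best = max(best, float(gamma @ phi_dot))
        act = find_active_constraints(sol.phi, system, None, 0.0)
        dcdt = system.drhs_rows(act.rows, None, 0.0, None)
        fb = select_forward_basis(sol, act, dcdt, gamma)
        assert np.isfinite(best), "no feasible-forward basis exists"
        assert gamma @ fb.phi_dot == pytest.approx(best, abs=1e-7)

    @pytest.mark.parametrize("seed", range(25))
    def test_selected_basis_satisfies_forward_conditions(self, seed):
        """Zero entries of w* get nonnegative rates; |J| = d with invertible B."""
        A, c0, cdot, gamma, _ = make_degenerate_lp(seed)
        system = _native_system(A, c0, cdot)
        sol, _ = solve_fba(system, gamma, None, 0.0)
        act = find_active_constraints(sol.phi, system, None, 0.0)
        dcdt = system.drhs_rows(act.rows, None, 0.0, None)
        fb = select_forward_basis(sol, act, dcdt, gamma)
        assert len(fb.row_subset) == system.d
        assert abs(np.linalg.det(fb.B_reduced)) > 1e-10
        # forward rates: slack rates of tight rows must be nonnegative,
        # variables at zero must not decrease
        sdot = np.asarray(cdot) - A @ fb.phi_dot
        for k in range(A.shape[0]):
            if abs(np.asarray(c0)[k] - A[k] @ sol.phi) <= 1e-8:
                assert sdot[k] >= -1e-8
        for j in range(system.d):
            if abs(sol.phi[j]) <= 1e-8:
                assert fb.phi_dot[j] >= -1e-8
        # the reduced system reproduces the current optimum at selection time
        np.testing.assert_allclose(fb.phi_at(None, 0.0), sol.phi, atol=1e-7)


class TestForwardFeasibility:
    def test_worked_basis_fails_just_past_switch(self, example1):
        system, gamma = example1
        sol, _ = solve_fba(system, gamma, None, 0.0)
        act = find_active_constraints(sol.phi, system, None, 0.0)
        fb = select_forward_basis(sol, act, [0.0, 0.0, -1.0], gamma)
        eps = 1e-3
        ok, violated = check_forward_feasibility(fb, system, None, 20.0 + eps)
        assert not ok
        # tracked solution is (10, -eps/2): the nonnegativity of v2 fails
        assert violated == [4]
        np.testing.assert_allclose(fb.phi_at(None, 20.0 + eps), [10.0, -eps / 2],
                                   atol=1e-9)

    def test_feasible_at_selection_time(self, example1):
        system, gamma = example1
        sol, _ = solve_fba(system, gamma, None, 0.0)
        act = find_active_constraints(sol.phi, system, None, 0.0)
        fb = select_forward_basis(sol, act, [0.0, 0.0, -1.0], gamma)
        ok, _ = check_forward_feasibility(fb, system, None, 0.0)
        assert ok

    def test_static_basis_fails_immediately(self, example1):
        """The basis pinning both variables at 10 breaks the shrinking row."""
        from dfbasis.lp import ForwardBasis
        import scipy.linalg

        system, gamma = example1
        B = np.eye(2)
        Q, R = scipy.linalg.qr(B)
        fb = ForwardBasis(active_rows=[0, 1], row_subset=[0, 1], B_reduced=B,
                          qr=(Q, R), system=system, phi_dot=np.zeros(2),
                          objective_rate=0.0)
        for t in (0.5, 5.0):
            ok, violated = check_forward_feasibility(fb, system, None, t)
            assert not ok and violated == [2]
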