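"""Event-driven integration: closed-form checks, event localization,
conservation/identity residuals, and determinism."""

import numpy as np
import pytest
import scipy.linalg

from dfbasis.dynamics import (
    CommunityState,
    ErrorOrderFixture,
    SimSettings,
    _Organism,
    empirical_error_order,
    error_curve,
    event_time_bisection,
    simulate,
    track_dynamic_lp,
)
from dfbasis.fixtures import make_example1, make_toy_community, make_toy_model
from dfbasis.lp import ForwardBasis, solve_fba
from dfbasis.model import ConstraintSystem, MetabolicModel, build_constraint_system


def _lp_only_state(system, gamma, basis):
    """Wrap a y-independent dynamic LP as a zero-exchange pseudo-organism."""
    model = MetabolicModel(
        species_id="lp", metabolite_ids=[], internal_metabolite_ids=[],
        Gamma_star=np.zeros((0, system.d)), Gamma_dagger=np.zeros((0, system.d)),
        gamma=gamma, exchange_map={}, reaction_ids=[f"v{j}" for j in range(system.d)],
    )
    org = _Organism(model=model, bounds=None, system=system,
                    met_idx=np.array([], dtype=int), basis=basis)
    return CommunityState(t=0.0, x=np.array([1.0]), y=np.zeros(0),
                          organisms=[org], alpha=np.zeros(0))


class TestStep:
    def test_constant_bounds_exponential_growth(self, toy_static):
        model, bounds, notes = toy_static
        # plenty of nutrient, short horizon: no events, pure exponential
        medium = {"met0": 1e3, "met1": 1e3}
        res = simulate([model], medium, [0.1], T=0.5,
                       settings=SimSettings(dt=0.01), bounds=[bounds])
        mu = notes["mu"]
        np.testing.assert_allclose(res.X[:, 0], 0.1 * np.exp(mu * res.times),
                                   rtol=1e-6)
        assert res.optimization_count["total"] == 1

    def test_zero_biomass_leaves_metabolites_unchanged(self, toy_static):
        model, bounds, _ = toy_static
        res = simulate([model], {"met0": 5.0, "met1": 5.0}, [0.0], T=1.0,
                       settings=SimSettings(dt=0.05), bounds=[bounds])
        np.testing.assert_allclose(res.Y, 5.0)
        np.testing.assert_allclose(res.X, 0.0)

    def test_identical_organisms_stay_symmetric(self):
        models, bounds, medium = make_toy_community(5, 2, 2, identical=True)
        res = simulate(models, medium, [0.2, 0.2], T=3.0,
                       settings=SimSettings(dt=0.05), bounds=bounds)
        np.testing.assert_allclose(res.X[:, 0], res.X[:, 1], rtol=1e-10)


class TestSimulate:
    def test_worked_lp_single_event_at_t20(self, example1):
        system, gamma = example1
        res = track_dynamic_lp(system, gamma, T=25.0, dt=0.5,
                               bisection=True, bisect_tol=1e-8)
        assert len(res.events) == 1
        assert res.events[0].time == pytest.approx(20.0, abs=1e-6)
        assert res.total_optimizations == 2

    def test_depletion_reaches_closed_form_biomass(self, toy_static):
        model, bounds, notes = toy_static
        y0, x0 = 10.0, 0.1
        t_dep = notes["depletion_time"](y0, x0)
        res = simulate([model], {"met0": y0, "met1": 10.0}, [x0], T=1.5 * t_dep,
                       settings=SimSettings(dt=0.02), bounds=[bounds])
        assert res.X[-1, 0] == pytest.approx(notes["final_biomass"](y0, x0), rel=1e-6)
        # biomass conserved after the depletion event
        k = np.searchsorted(res.times, t_dep) + 1
        np.testing.assert_allclose(res.X[k:, 0], res.X[-1, 0], rtol=1e-5)
        assert res.Y[-1, 0] == pytest.approx(0.0, abs=1e-6)

    def test_essential_nutrient_absent_means_no_growth(self, toy_static):
        model, bounds, _ = toy_static
        res = simulate([model], {"met0": 0.0, "met1": 10.0}, [0.3], T=1.0,
                       settings=SimSettings(dt=0.05), bounds=[bounds])
        np.testing.assert_allclose(res.X[:, 0], 0.3, rtol=1e-12)

    def test_empty_model_list(self):
        res = simulate([], {}, [], T=1.0)
        assert res.total_optimizations == 0
        assert res.X.shape[1] == 0

    def test_determinism_of_event_logs(self, toy_community):
        models, bounds, medium = toy_community
        runs = [simulate(models, medium, [0.3, 0.3], T=4.0,
                         settings=SimSettings(dt=0.05), bounds=bounds)
                for _ in range(2)]
        log0 = [(e.time, e.organism, tuple(e.new_J)) for e in runs[0].events]
        log1 = [(e.time, e.organism, tuple(e.new_J)) for e in runs[1].events]
        assert log0 == log1
        np.testing.assert_array_equal(runs[0].X, runs[1].X)

    def test_counting_matches_event_log(self, toy_community):
        models, bounds, medium = toy_community
        res = simulate(models, medium, [0.3, 0.3], T=4.0,
                       settings=SimSettings(dt=0.05), bounds=bounds)
        for m in models:
            n_events = sum(e.organism == m.species_id for e in res.events)
            assert res.optimization_count[m.species_id] == 1 + n_events


@pytest.fixture(scope="module")
def community_run():
    models, bounds, medium = make_toy_community(11, 2, 2, 2, uptake="linear")
    res = simulate(models, medium, [0.3, 0.2], T=4.0,
                   settings=SimSettings(dt=0.02), bounds=bounds)
    return models, bounds, medium, res


class TestInvariants:
    def test_tracked_objective_matches_fresh_solve(self, community_run):
        """At 20 random accepted times the basis objective equals a fresh FBA."""
        models, bounds, medium, res = community_run
        rng = np.random.default_rng(0)
        picks = rng.choice(len(res.times), size=20, replace=False)
        for i, m in enumerate(models):
            system = build_constraint_system(m, bounds[i])
            for k in picks:
                y = res.Y[k]
                tracked = float(m.gamma @ res.Phi[i][k])
                sol, _ = solve_fba(system, m.gamma, y, res.times[k])
                assert tracked == pytest.approx(sol.objective, rel=1e-6, abs=1e-9)

    def test_growth_identity_and_metabolite_bookkeeping(self, community_run):
        """d/dt log x = gamma.phi and dy/dt = -sum x psi along the trajectory."""
        models, _, _, res = community_run
        t = res.times
        for i, m in enumerate(models):
            mus = res.Phi[i] @ m.gamma
            dlnx = np.diff(np.log(res.X[:, i]))
            trap = 0.5 * (mus[1:] + mus[:-1]) * np.diff(t)
            # residual limited by the trapezoid quadrature, not the integrator
            np.testing.assert_allclose(dlnx, trap, atol=5e-3)
        uptake = np.zeros_like(res.Y)
        for i, m in enumerate(models):
            uptake += res.X[:, [i]] * (res.Phi[i] @ m.Gamma_star.T)
        dy = np.diff(res.Y, axis=0)
        trap = -0.5 * (uptake[1:] + uptake[:-1]) * np.diff(t)[:, None]
        np.testing.assert_allclose(dy, trap, atol=5e-3)

    def test_metabolites_never_go_negative(self, community_run):
        *_, res = community_run
        assert res.Y.min() >= -1e-8


class TestEventBisection:
    def test_worked_example_bracket(self, example1):
        system, gamma = example1
        sol, _ = solve_fba(system, gamma, None, 0.0)
        from dfbasis.lp import find_active_constraints, select_forward_basis
        act = find_active_constraints(sol.phi, system, None, 0.0)
        fb = select_forward_basis(sol, act, [0.0, 0.0, -1.0], gamma)
        state = _lp_only_state(system, gamma, fb)
        t_star = event_time_bisection(fb, state, 19.0, 21.0, tol=1e-7)
        assert t_star == pytest.approx(20.0, abs=1e-6)

    def test_feasible_at_both_ends_rejected(self, example1):
        system, gamma = example1
        sol, _ = solve_fba(system, gamma, None, 0.0)
        from dfbasis.lp import find_active_constraints, select_forward_basis
        act = find_active_constraints(sol.phi, system, None, 0.0)
        fb = select_forward_basis(sol, act, [0.0, 0.0, -1.0], gamma)
        state = _lp_only_state(system, gamma, fb)
        with pytest.raises(ValueError, match="both bracket ends"):
            event_time_bisection(fb, state, 1.0, 5.0, tol=1e-7)

    def test_linear_slack_analytic_root(self):
        """Tracked variable 1 - t/2 crosses zero at exactly t = 2."""
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        system = ConstraintSystem(
            A=A, c_of=lambda y, t: np.array([1.0 - t / 2.0, 5.0]), n=2,
            Gamma_dagger=np.zeros((0, 2)), row_labels=["a", "b"],
            dc_of=lambda y, t, yd: np.array([-0.5, 0.0]), nonneg=True)
        gamma = np.array([1.0, 1.0])
        sol, _ = solve_fba(system, gamma, None, 0.0)
        from dfbasis.lp import find_active_constraints, select_forward_basis
        act = find_active_constraints(sol.phi, system, None, 0.0)
        fb = select_forward_basis(sol, act, system.drhs_rows(act.rows, None, 0, None),
                                  gamma)
        state = _lp_only_state(system, gamma, fb)
        t_star = event_time_bisection(fb, state, 0.0, 4.0, tol=1e-8)
        assert t_star == pytest.approx(2.0, abs=1e-6)


@pytest.fixture(scope="module")
def curves():
    fx = ErrorOrderFixture()
    dts = fx.default_dts()
    return (fx, dts, error_curve(fx, dts, bisection=False),
            error_curve(fx, dts, bisection=True))


class TestErrorOrder:
    def test_unlocalised_events_give_first_order(self, curves):
        fx, dts, e_no, _ = curves
        slope = np.polyfit(np.log(dts), np.log(e_no), 1)[0]
        assert 0.8 <= slope <= 1.2

    def test_bisection_strictly_reduces_error(self, curves):
        _, _, e_no, e_bi = curves
        assert (e_bi < e_no).all()

    def test_no_event_control_is_integrator_limited(self, toy_static):
        """Without an event in the horizon the error is far below first order."""
        model, bounds, notes = toy_static
        medium = {"met0": 1e3, "met1": 1e3}
        errs = []
        for dt in (0.1, 0.05, 0.025):
            res = simulate([model], medium, [0.1], T=0.5,
                           settings=SimSettings(dt=dt), bounds=[bounds])
            errs.append(abs(res.X[-1, 0] - 0.1 * np.exp(notes["mu"] * 0.5)))
        slope = np.polyfit(np.log([0.1, 0.05, 0.025]), np.log(errs), 1)[0]
        assert slope >= 3.0  # fourth-order smooth-phase integrator

    def test_too_few_step_sizes_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            empirical_error_order(None, [0.1, 0.05])
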