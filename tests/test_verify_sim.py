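import numpy as np
import pytest
import sympy as sp

from acwave import wave_solvers as W
from acwave.model import BACModel, make_bac_model
from acwave.reductions import r
from acwave.jets import t as T, x as X, y as Y
from acwave import verify_sim as V
from conftest import find_set

d, g, s = W.d_sym, W.gamma_sym, W.sigma_sym


class TestResidualReport:
    def test_equilibrium_profile(self, ode18):
        rep = V.residual_report(sp.S.One, ode18)
        assert rep.symbolic_status == "zero"
        assert rep.numeric_max_abs == 0.0

    def test_derived_kink_satisfies_ode(self, tanh_solution, ode28):
        _, sets = tanh_solution
        ps = find_set(sets, {W.a0: (s + 1) / 2,
                             sp.Symbol("b1"): sp.S.Zero})
        case = [c for c in W.tanh_library() if c.case == "k_neg_tanh"][0]
        sol = W.assemble_solutions(ps, [case])[0]
        rep = V.residual_report(sol, ode28, constraints=ps.assignments)
        assert rep.symbolic_status == "zero"

    def test_printed_kink_set_residual_vanishes_at_sigma_zero(self, ode28):
        printed = [p for p in W.paper_sets("tanh") if p.source_eq == 123][0]
        case = [c for c in W.tanh_library() if c.case == "k_neg_tanh"][0]
        sol = W.assemble_solutions(printed, [case])[0]
        rep = V.residual_report(sol, ode28, constraints=printed.assignments)
        assert rep.symbolic_status == "nonzero"
        rep0 = V.residual_report(
            sp.sympify(sol.expression).subs(s, 0),
            ode28.subs_params({s: 0}),
            constraints={k: sp.sympify(v).subs(s, 0)
                         for k, v in printed.assignments.items()})
        assert rep0.symbolic_status == "zero"

    def test_pde_target(self, tanh_solution, model):
        _, sets = tanh_solution
        ps = find_set(sets, {W.a0: (s + 1) / 2,
                             sp.Symbol("b1"): sp.S.Zero})
        case = [c for c in W.tanh_library() if c.case == "k_neg_tanh"][0]
        sol = W.assemble_solutions(ps, [case],
                                   r_definition=T - X - Y)[0]
        constrained = BACModel(model.d,
                               sp.sympify(ps.get(g)), model.sigma)
        rep = V.residual_report(sol, constrained,
                                constraints=ps.assignments)
        assert rep.symbolic_status == "zero"


class TestSimulator:
    def test_uniform_equilibrium_is_stationary(self):
        m = make_bac_model(d=1, gamma=1, sigma=0.4)
        sim = V.simulate_1d(m, 1.0, lambda x: np.full_like(x, 0.4),
                            x_span=(-10, 10), n_points=101, t_end=2.0,
                            n_samples=5)
        assert np.allclose(sim.fields[-1], 0.4, atol=1e-12)

    def test_pointwise_dynamics_without_diffusion(self):
        # D = 0, sigma < u0 < 1: the bistable reaction pushes M toward 1
        m = make_bac_model(d=1, gamma=2, sigma=0.3)
        sim = V.simulate_1d(m, 0.0, lambda x: np.full_like(x, 0.6),
                            x_span=(-1, 1), n_points=11, t_end=15.0,
                            n_samples=4)
        assert np.allclose(sim.fields[-1], 1.0, atol=1e-6)
        # reference: scipy integration of the scalar reaction ODE
        from scipy.integrate import solve_ivp

        f = lambda t_, m_: -2.0 * m_ * (m_ - 1.0) * (m_ - 0.3)
        ref = solve_ivp(f, (0, 15.0), [0.6], rtol=1e-10, atol=1e-12)
        assert abs(sim.fields[-1][0] - ref.y[0, -1]) < 1e-6

    def test_mass_conserved_when_reaction_off(self):
        m = make_bac_model(d=1, gamma=sp.Float(1e-30), sigma=0.5)
        m = BACModel(1, 0.0 + 1e-300, 0.5)  # reaction numerically off
        rng = np.random.default_rng(0)
        u0 = 0.5 + 0.2 * np.sin(np.linspace(0, 4 * np.pi, 201))
        sim = V.simulate_1d(m, 0.5, u0, x_span=(-5, 5), n_points=201,
                            t_end=1.0, n_samples=5)
        means = sim.fields.mean(axis=1)
        assert np.allclose(means, means[0], atol=1e-10)

    def test_instability_detected(self):
        m = make_bac_model(d=1, gamma=1, sigma=0.5)
        with pytest.raises(V.SimulationUnstable):
            # gigantic time horizon with an enormous initial amplitude
            V.simulate_1d(m, 1.0, lambda x: 50.0 * np.sign(x),
                          x_span=(-5, 5), n_points=51, t_end=5.0,
                          n_samples=3)

    def test_grid_refinement_second_order(self):
        model, deff, prof = V.derived_kink(0.5, 0.3)
        f = sp.lambdify(r, prof, "numpy")
        errs = []
        for n in (201, 401):
            sim = V.simulate_1d(model, deff, lambda xx: f(-xx),
                                x_span=(-30, 30), n_points=n, t_end=2.0,
                                n_samples=3)
            exact = f(sim.times[-1] - sim.x)
            errs.append(np.abs(sim.fields[-1] - exact).max())
        ratio = errs[0] / errs[1]
        assert 2.5 < ratio < 6.0  # ~4x per halving of h


class TestSpeed:
    def test_recovers_constructed_translation(self):
        x = np.linspace(-20, 20, 801)
        times = np.linspace(0, 5, 11)
        v_true = 0.731
        fields = np.array([np.tanh(x - v_true * tt) * 0.5 + 0.5
                           for tt in times])
        sim = V.SimResult(x=x, times=times, fields=fields)
        est = V.measure_speed(sim, level=0.5)
        assert abs(est.speed - v_true) < 1e-6

    def test_stationary_profile_has_no_crossing(self):
        x = np.linspace(-5, 5, 101)
        times = np.linspace(0, 1, 3)
        fields = np.full((3, 101), 0.4)
        sim = V.SimResult(x=x, times=times, fields=fields)
        with pytest.raises(V.CrossingError):
            V.measure_speed(sim, level=0.65)

    def test_multiple_crossings_rejected(self):
        x = np.linspace(-5, 5, 401)
        times = np.linspace(0, 1, 3)
        fields = np.array([np.sin(2 * x) for _ in times])
        sim = V.SimResult(x=x, times=times, fields=fields)
        with pytest.raises(V.CrossingError):
            V.measure_speed(sim, level=0.1)

    def test_derived_kink_travels_at_unit_speed(self):
        model, deff, prof = V.derived_kink(0.5, 0.3)
        f = sp.lambdify(r, prof, "numpy")
        sim = V.simulate_1d(model, deff, lambda xx: f(-xx),
                            x_span=(-40, 60), n_points=1001, t_end=25.0,
                            n_samples=11)
        est = V.measure_speed(sim, level=0.65)
        assert abs(est.speed - 1.0) < 0.02
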