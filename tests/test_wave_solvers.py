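import pytest
import sympy as sp

from acwave import wave_solvers as W
from acwave.reductions import OrdODE, r, u
from conftest import find_set

d, g, s = W.d_sym, W.gamma_sym, W.sigma_sym
a0, a1 = W.a0, W.a1
b1t = sp.Symbol("b1")


class TestBalance:
    @pytest.mark.parametrize("method", W.METHODS)
    @pytest.mark.parametrize("ode_fix", ["ode13", "ode18", "ode23", "ode28"])
    def test_cubic_odes_balance_to_one(self, method, ode_fix, request):
        ode = request.getfixturevalue(ode_fix)
        assert W.homogeneous_balance(ode, method) == 1

    def test_quadratic_nonlinearity(self):
        U = u(r)
        ode = OrdODE(sp.Derivative(U, r, 2) + U**2)
        assert W.homogeneous_balance(ode, "tanh") == 2

    def test_quartic_nonlinearity_inapplicable(self):
        U = u(r)
        ode = OrdODE(sp.Derivative(U, r, 2) + U**4)
        with pytest.raises(W.BalanceError):
            W.homogeneous_balance(ode, "aux")


class TestLibraries:
    @pytest.mark.parametrize("entry", W.aux_library(),
                             ids=lambda e: f"eq{e.source_eq}:{e.branch:+d}")
    def test_aux_entries_satisfy_quartic_relation(self, entry):
        assert W.library_residual_status(entry) == "zero"

    @pytest.mark.parametrize("case", W.gg2_library(), ids=lambda c: c.case)
    def test_gg2_cases_satisfy_riccati(self, case):
        assert W.library_residual_status(case) == "zero"

    @pytest.mark.parametrize("case", W.tanh_library(), ids=lambda c: c.case)
    def test_tanh_cases_satisfy_relation(self, case):
        assert W.library_residual_status(case) == "zero"

    def test_family_counts(self):
        assert len({e.source_eq for e in W.aux_library()}) == 16
        assert len(W.gg2_library()) == 3
        assert len(W.tanh_library()) == 5

    def test_degenerate_limit_entry(self):
        # zeta = 0 family: -(b1/b2)*(1 +- tanh(...))
        e39 = [e for e in W.aux_library() if e.source_eq == 39
               and e.branch == 1][0]
        expected = -(W.b1 / W.b2) * (1 + sp.tanh(sp.sqrt(W.b1) / 2 * r))
        assert sp.simplify(e39.closed_form - expected) == 0

    def test_rational_entry(self):
        e48 = [e for e in W.aux_library() if e.source_eq == 48][0]
        assert sp.simplify(e48.closed_form * sp.sqrt(W.b3) * r
                           - e48.branch) == 0

    def test_tanh_kappa_zero_case(self):
        c = [c for c in W.tanh_library() if c.case == "k_zero"][0]
        assert c.closed_form == -1 / r


class TestAlgebraicSystem:
    def test_leading_tanh_coefficient(self, tanh_solution):
        """On the doubled-diffusion ODE the top coefficient forces
        gamma*a1^2 = 4*d (with the reciprocal part switched off)."""
        system, _ = tanh_solution
        tops = [sp.factor(e.subs(b1t, 0)) for e in system.equations]
        target = sp.factor(a1 * (a1**2 * g - 4 * d))
        assert any(sp.simplify(e - target) == 0 or
                   sp.simplify(e + target) == 0 for e in tops)

    def test_gg2_quadratic_coefficient(self, gg2_solution):
        system, _ = gg2_solution
        target = sp.factor(a1 * (W.kappa + g * a1 * (3 * a0 - 1 - s)))
        assert any(sp.simplify(sp.factor(e) - target) == 0 or
                   sp.simplify(sp.factor(e) + target) == 0
                   for e in system.equations)

    @pytest.mark.parametrize("fixture", ["aux_solution", "gg2_solution",
                                         "tanh_solution"])
    def test_zero_ansatz_is_trivial_solution(self, fixture, request):
        system, _ = request.getfixturevalue(fixture)
        zeros = dict.fromkeys(system.coefficients, 0)
        assert all(sp.simplify(e.subs(zeros)) == 0
                   for e in system.equations)


class TestDerivedSets:
    def test_gg2_front_branch(self, gg2_solution):
        _, sets = gg2_solution
        ps = find_set(sets, {a0: (s + 1) / 2})
        assert sp.simplify(ps.get(a1) + 2 * W.kappa / (g * (s + 1))) == 0
        assert sp.simplify(ps.get(d) - 2 / (g * (s + 1)**2)) == 0
        tau_derived = -g**2 * (s - 1)**2 * (s + 1)**2 / (16 * W.kappa)
        assert sp.simplify(ps.get(W.tau) - tau_derived) == 0

    def test_gg2_branch_completeness(self, gg2_solution):
        _, sets = gg2_solution
        a0_values = {sp.simplify(ps.get(a0)) for ps in sets}
        assert {(s + 1) / 2, s / 2, sp.Rational(1, 2)} <= {
            sp.simplify(v) for v in a0_values}

    def test_tanh_pure_and_reciprocal_branches(self, tanh_solution):
        _, sets = tanh_solution
        pure = find_set(sets, {a0: (s + 1) / 2, b1t: sp.S.Zero})
        assert sp.simplify(pure.get(a1) + 2 * d * (s + 1)) == 0
        assert sp.simplify(pure.get(g) - 1 / (d * (s + 1)**2)) == 0
        kap = -(s - 1)**2 / (16 * d**2 * (s + 1)**2)
        assert sp.simplify(pure.get(W.kappa) - kap) == 0
        mixed = find_set(sets, {
            a0: (s + 1) / 2,
            b1t: -(s - 1)**2 / (32 * d * (s + 1))})
        assert sp.simplify(mixed.get(W.kappa)
                           + (s - 1)**2 / (64 * d**2 * (s + 1)**2)) == 0

    def test_aux_branch_completeness(self, aux_solution):
        _, sets = aux_solution
        a0_values = [sp.simplify(ps.get(a0)) for ps in sets]
        assert sp.S.Zero in a0_values
        assert sp.S.One in a0_values
        # the remaining family has a0 = sigma (both printed identically)
        tied = [ps for ps in sets
                if sp.simplify(ps.get(a0) - ps.get(s)) == 0
                and ps.get(a0) not in (0, 1)]
        assert tied

    def test_aux_set1_matches_printed_gamma(self, aux_solution):
        _, sets = aux_solution
        tied = [ps for ps in sets
                if sp.simplify(ps.get(a0) - ps.get(s)) == 0
                and ps.get(a0) not in (0, 1)]
        printed_gamma = 9 * W.b2**2 * d / (2 * W.b3) - 16 * W.b1 * d
        for ps in tied:
            assert sp.simplify(ps.get(g) - printed_gamma) == 0

    @pytest.mark.parametrize("fixture", ["aux_solution", "gg2_solution",
                                         "tanh_solution"])
    def test_all_returned_sets_verified(self, fixture, request):
        _, sets = request.getfixturevalue(fixture)
        assert sets  # at least one non-degenerate branch
        assert all(ps.residual_status in ("zero", "undecided")
                   for ps in sets)
        assert any(ps.residual_status == "zero" for ps in sets)


class TestPaperSets:
    def test_catalog_shape(self):
        all_sets = W.paper_sets()
        assert {ps.source_eq for ps in all_sets} == {62, 79, 96, 114, 118,
                                                     123, 130}
        assert all(ps.provenance == "paper" for ps in all_sets)

    def test_sigma_zero_concordance_gg2(self, gg2_solution):
        _, sets = gg2_solution
        derived = find_set(sets, {a0: (s + 1) / 2})
        printed = [p for p in W.paper_sets("gg2") if p.source_eq == 114][0]
        for sym in (a0, a1, d):
            assert sp.simplify(derived.get(sym) - printed.get(sym)) == 0
        diff_tau = derived.get(W.tau) - printed.get(W.tau)
        assert sp.simplify(diff_tau) != 0             # generic mismatch
        assert sp.simplify(diff_tau.subs(s, 0)) == 0  # sigma = 0 agreement

    def test_sigma_zero_concordance_tanh(self, tanh_solution):
        _, sets = tanh_solution
        derived = find_set(sets, {a0: (s + 1) / 2, b1t: sp.S.Zero})
        printed = [p for p in W.paper_sets("tanh") if p.source_eq == 123][0]
        for sym in (a0, a1, g):
            assert sp.simplify(derived.get(sym) - printed.get(sym)) == 0
        diff_k = derived.get(W.kappa) - printed.get(W.kappa)
        assert sp.simplify(diff_k) != 0
        assert sp.simplify(diff_k.subs(s, 0)) == 0

    def test_alpha0_equals_sigma_in_steady_set(self):
        ps = [p for p in W.paper_sets("aux") if p.source_eq == 62][0]
        assert sp.simplify(ps.get(a0) - ps.get(s)) == 0


class TestAssembly:
    def test_reciprocal_linear_family_reproduced(self):
        """Paper gg2 set + printed rational case reproduces the printed
        family: the a1 factor multiplies -A1/(tau*(A1*r + B1))."""
        printed = [p for p in W.paper_sets("gg2") if p.source_eq == 114][0]
        case = [c for c in W.gg2_library() if c.case == "tau_zero"][0]
        sol = W.assemble_solutions(printed, [case])[0]
        expected = ((s + 1) / 2
                    + (-2 * W.kappa / (g * s + g))
                    * (-W.A1 / (W.tau * (W.A1 * r + W.B1))))
        expected = expected.subs(W.tau, printed.get(W.tau))
        assert sp.simplify(sol.expression - expected) == 0

    def test_kink_family_reproduced(self):
        printed = [p for p in W.paper_sets("tanh") if p.source_eq == 123][0]
        case = [c for c in W.tanh_library() if c.case == "k_neg_tanh"][0]
        sol = W.assemble_solutions(printed, [case])[0]
        kap_expr = printed.get(W.kappa)
        expected = ((s + 1) / 2 + (-2 * d * (s + 1))
                    * (-sp.sqrt(-W.kappa) * sp.tanh(sp.sqrt(-W.kappa) * r)))
        expected = expected.subs(W.kappa, kap_expr)
        assert sp.simplify(sol.expression - expected) == 0

    def test_vacuous_flagging(self, tanh_solution):
        _, sets = tanh_solution
        derived = find_set(sets, {a0: (s + 1) / 2, b1t: sp.S.Zero})
        sols = W.assemble_solutions(derived, W.tanh_library())
        by_case = {sol.entry_eq: sol for sol in sols}
        # kappa < 0 for this set, so the tan/cot (kappa > 0) cases are
        # incompatible and flagged, never dropped
        assert by_case[59].vacuous and by_case[60].vacuous
        assert not by_case[56].vacuous
        assert len(sols) == 5

    def test_derived_kink_connects_equilibria(self, tanh_solution):
        _, sets = tanh_solution
        derived = find_set(sets, {a0: (s + 1) / 2, b1t: sp.S.Zero})
        case = [c for c in W.tanh_library() if c.case == "k_neg_tanh"][0]
        sol = W.assemble_solutions(derived, [case])[0]
        prof = sol.expression.subs({d: sp.Rational(1, 2),
                                    s: sp.Rational(3, 10)})
        lims = {sp.limit(prof, r, sp.oo), sp.limit(prof, r, -sp.oo)}
        assert lims == {sp.Rational(3, 10), 1}


class TestClassification:
    @pytest.mark.parametrize("expr, label", [
        (sp.tanh(r), "kink"),
        (-sp.tanh(r), "anti-kink"),
        (sp.Rational(1, 2) + sp.sech(r), "bright"),
        (sp.Rational(1, 2) - sp.sech(r), "dark"),
        (sp.sin(2 * r), "periodic"),
        (sp.tan(r), "periodic"),
        (sp.coth(r), "singular"),
        (1 / r, "rational"),
        (sp.S.One, "constant"),
    ], ids=str)
    def test_profile_shapes(self, expr, label):
        assert W.classify_solution(expr) == label

    def test_free_parameters_rejected(self):
        with pytest.raises(ValueError):
            W.classify_solution(W.kappa * sp.tanh(r))
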