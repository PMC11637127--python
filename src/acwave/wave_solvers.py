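"""Expansion-method solvers for the reduced travelling-wave ODEs.

Three classical methods are implemented end to end:

* the generalized auxiliary equation method, seeded by the quartic
  relation (ς')² = b₁ς² + b₂ς³ + b₃ς⁴ and its sixteen closed-form
  solution families (hyperbolic, trigonometric, exponential, rational);
* the modified (G'/G²)-expansion method, seeded by the Riccati equation
  H' = τ + κH² for the ratio variable H = G'/G²;
* the extended modified tanh method, seeded by ς' = κ + ς².

For each method: the homogeneous-balance rule fixes the truncation
order N (N = 1 for the cubic ODEs here); substituting the truncated
ansatz and eliminating auxiliary derivatives yields a polynomial system
for the coefficients; all solution branches are found by recursive
elimination with leading-coefficient case splits; each derived set is
verified by exact back-substitution.  Assembling a set with a library
entry produces an explicit closed-form solution which can be classified
(kink, bright, dark, periodic, singular, rational) from its numeric
profile.

Several library entries and reference parameter sets are carried in two
forms: the algebraically sound form used for computation, and the
as-printed form from the reference tables (`provenance="paper"`), whose
residuals are reported rather than assumed zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import sympy as sp

from .model import DEFAULT_SYMBOLS
from .reductions import OrdODE, r, u
from .ztest import zero_status

__all__ = [
    "AuxLibraryEntry", "GG2Case", "TanhCase", "ParameterSet",
    "ClosedFormSolution", "homogeneous_balance", "expansion_ansatz",
    "build_algebraic_system", "solve_parameter_sets", "aux_library",
    "gg2_library", "tanh_library", "paper_sets", "assemble_solutions",
    "classify_solution",
]

d_sym, gamma_sym, sigma_sym = DEFAULT_SYMBOLS

#: auxiliary-function value and (for the quartic method) its derivative
S = sp.Symbol("varsigma")
Sp = sp.Symbol("varsigma_prime")

b1, b2, b3 = sp.symbols("b1 b2 b3", real=True)
kappa, tau = sp.symbols("kappa tau", real=True)
A1, B1 = sp.symbols("A1 B1", real=True, nonzero=True)

zeta = b2**2 - 4 * b1 * b3

METHODS = ("aux", "gg2", "tanh")


# --------------------------------------------------------------------------
# homogeneous balance

def homogeneous_balance(ode: OrdODE, method: str = "aux") -> int:
    """Truncation order N from balancing u'' against the top nonlinearity.

    All three auxiliary relations raise the effective ς-degree by one per
    derivative (ς' ~ ς²), so a term u^(k) has degree N + k and u^m has
    degree m*N; equating the two largest degrees gives N.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    expr = sp.expand(ode.expression)
    U = u(r)
    p_max = 0      # highest derivative order present
    m_max = 1      # highest pure power of u
    mixed = []     # (derivative order sum, u-power) per term
    for term in sp.Add.make_args(expr):
        dsum, upow = 0, 0
        for fac in sp.Mul.make_args(term):
            base, ex = fac.as_base_exp()
            if isinstance(base, sp.Derivative):
                dsum += base.derivative_count * int(ex)
                upow += int(ex)
            elif base == U:
                upow += int(ex)
        if dsum:
            p_max = max(p_max, dsum)
        elif upow:
            m_max = max(m_max, upow)
        mixed.append((dsum, upow))
    if p_max == 0 or m_max < 2:
        raise BalanceError("no derivative/nonlinearity pair to balance")
    N = sp.Rational(p_max, m_max - 1)
    if not (N.is_integer and N > 0):
        raise BalanceError(
            f"balance gives N = {N}; the method is inapplicable")
    return int(N)


class BalanceError(ValueError):
    pass


# --------------------------------------------------------------------------
# ansatz construction and derivative elimination

def expansion_ansatz(method: str, N: int):
    """(ansatz expression in S, list of coefficient symbols)."""
    a = sp.symbols(f"a0:{N + 1}")
    expr = a[0] + sum(a[i] * S**i for i in range(1, N + 1))
    coeffs = list(a)
    if method == "tanh":
        b = sp.symbols(f"b1:{N + 1}")
        expr += sum(b[i - 1] * S**-i for i in range(1, N + 1))
        coeffs += list(b)
    return expr, coeffs


def _aux_Q():
    return b1 * S**2 + b2 * S**3 + b3 * S**4


def _d_dr(expr, method):
    """Derivative along r of an expression in (S, Sp) under the method's
    auxiliary relation, reduced so that Sp appears at most linearly."""
    if method == "aux":
        Q = _aux_Q()
        out = sp.diff(expr, S) * Sp + sp.diff(expr, Sp) * sp.diff(Q, S) / 2
        # reduce even powers of Sp via Sp**2 = Q
        p = sp.Poly(sp.expand(out), Sp)
        red = sp.S.Zero
        for (k,), c in p.terms():
            red += c * (Q ** (k // 2)) * (Sp ** (k % 2))
        return sp.expand(red)
    rate = tau + kappa * S**2 if method == "gg2" else kappa + S**2
    return sp.expand(sp.diff(expr, S) * rate)


@dataclass
class AlgebraicSystem:
    """Coefficient equations from substituting a truncated ansatz."""

    equations: list
    unknowns: list
    method: str
    N: int
    ansatz: sp.Expr
    coefficients: list
    ode: OrdODE


def build_algebraic_system(ode: OrdODE, method: str, N: int
                           ) -> AlgebraicSystem:
    """Substitute the ansatz, eliminate auxiliary derivatives, collect.

    The result is the polynomial system in the ansatz coefficients (and
    any model symbols the set determines) obtained by equating to zero
    every coefficient of the powers of the auxiliary function — and, for
    the quartic method, of its derivative, which survives linearly.
    """
    U_ans, coeffs = expansion_ansatz(method, N)
    u1 = _d_dr(U_ans, method)
    u2 = _d_dr(u1, method)
    expr = ode.expression.subs(
        {sp.Derivative(u(r), r, 2): u2, sp.Derivative(u(r), r): u1,
         u(r): U_ans}, simultaneous=True)
    expr = sp.expand(sp.numer(sp.together(sp.expand(expr))))
    eqs = []
    if method == "aux":
        p = sp.Poly(expr, Sp)
        parts = [p.coeff_monomial(Sp**k) for k in range(p.degree() + 1)]
    else:
        parts = [expr]
    for part in parts:
        if part == 0:
            continue
        for c in sp.Poly(sp.expand(part), S).all_coeffs():
            if c != 0:
                eqs.append(sp.expand(c))
    model_candidates = {
        "aux": [gamma_sym, sigma_sym],
        "gg2": [d_sym, tau],
        "tanh": [kappa, gamma_sym],
    }[method]
    free = expr.free_symbols
    unknowns = list(coeffs) + [s for s in model_candidates if s in free]
    return AlgebraicSystem(eqs, unknowns, method, N, U_ans, coeffs, ode)


# --------------------------------------------------------------------------
# algebraic solving: recursive elimination with case splits

def _pivot_key(e, v, present):
    n_unk = sum(1 for q in present if e.has(q))
    try:
        return (n_unk, sp.degree(e, v), sp.count_ops(e))
    except sp.PolynomialError:
        return (n_unk, 100, sp.count_ops(e))


def _solve_rec(eqs, unknowns, depth=0, max_depth=14):
    if depth > max_depth:
        return []
    cleaned = []
    for e in eqs:
        e = sp.expand(sp.numer(sp.together(e)))
        if e.is_zero:
            continue
        if e.is_number:
            if sp.simplify(e) != 0:
                return []
            continue
        cleaned.append(e)
    if not cleaned:
        return [dict()]
    present = [q for q in unknowns if any(e.has(q) for e in cleaned)]
    if not present:
        # residual depends only on free parameters: zero-test it
        if all(zero_status(e) == "zero" for e in cleaned):
            return [dict()]
        return []
    best = min(((e, v) for e in cleaned for v in present if e.has(v)),
               key=lambda ev: _pivot_key(ev[0], ev[1], present), default=None)
    if best is None:
        return []
    e, v = best
    rest = [q for q in cleaned if q is not e]
    out = []
    try:
        roots = sp.solve(e, v, dict=False)
    except Exception:
        roots = []
    for val in roots:
        sub = [q.subs(v, val) for q in rest]
        for tail in _solve_rec(sub, [q for q in unknowns if q != v],
                               depth + 1, max_depth):
            sol = {v: sp.simplify(val.subs(tail))}
            sol.update(tail)
            out.append(sol)
    try:
        p = sp.Poly(e, v)
    except sp.PolynomialError:
        p = None
    if p is not None and p.degree() >= 1:
        lc = p.LC()
        if any(lc.has(q) for q in unknowns):
            deg = p.degree()
            out += _solve_rec([lc, sp.expand(e - lc * v**deg)] + rest,
                              unknowns, depth + 1, max_depth)
    return out


@dataclass
class ParameterSet:
    """Solved expansion coefficients plus induced parameter constraints."""

    assignments: dict
    method: str
    provenance: str = "derived"          # derived | paper
    source_eq: int | None = None
    branch: tuple = ()
    residual_status: str | None = None   # zero | nonzero | undecided
    notes: str = ""

    def get(self, sym, default=None):
        return self.assignments.get(sym, default)

    def expansion_coefficients(self, N=1):
        names = [f"a{i}" for i in range(N + 1)] + [f"b{i}"
                                                   for i in range(1, N + 1)]
        return {str(k): v for k, v in self.assignments.items()
                if str(k) in names}

    def is_degenerate(self, N=1) -> bool:
        coeffs = self.expansion_coefficients(N)
        lead = {k: v for k, v in coeffs.items() if k != "a0"}
        return all(sp.simplify(v) == 0 for v in lead.values()) if lead \
            else True

    def __str__(self):
        items = ", ".join(f"{k} = {sp.sstr(v)}"
                          for k, v in sorted(self.assignments.items(),
                                             key=lambda kv: str(kv[0])))
        tag = self.provenance + (f" set {self.source_eq}"
                                 if self.source_eq else "")
        return f"<ParameterSet {self.method} [{tag}] {items}>"


class SetList(list):
    """List of parameter sets; bookkeeping for discarded branches."""

    degenerate_count: int = 0
    spurious_count: int = 0


def solve_parameter_sets(system: AlgebraicSystem, seed: int = 0) -> SetList:
    """All non-degenerate solution branches, each verified exactly.

    Branches whose back-substituted residuals fail the zero test are
    counted as spurious (artifacts of radical equations) and dropped;
    constant branches (all leading coefficients zero) are counted and
    dropped; everything returned satisfies the generating system.
    """
    raw = _solve_rec(system.equations, system.unknowns)
    out = SetList()
    seen = set()
    for sol in raw:
        pset = ParameterSet({k: sp.simplify(v) for k, v in sol.items()},
                            system.method)
        if pset.is_degenerate(system.N):
            out.degenerate_count += 1
            continue
        key = tuple(sorted((str(k), sp.srepr(sp.factor(v)))
                           for k, v in pset.assignments.items()))
        if key in seen:
            continue
        seen.add(key)
        statuses = [zero_status(e.subs(pset.assignments), seed=seed)
                    for e in system.equations]
        if any(st == "nonzero" for st in statuses):
            out.spurious_count += 1
            continue
        pset.residual_status = ("zero" if all(st == "zero"
                                              for st in statuses)
                                else "undecided")
        out.append(pset)
    return out


# --------------------------------------------------------------------------
# auxiliary-function libraries

@dataclass(frozen=True)
class AuxLibraryEntry:
    """One closed-form solution of (ς')² = b₁ς² + b₂ς³ + b₃ς⁴."""

    source_eq: int
    family: str                    # hyperbolic | trigonometric | ...
    closed_form: sp.Expr           # sound form, in (r, b1, b2, b3)
    validity: tuple                # sympy relationals / equalities
    branch: int = +1
    corrected: bool = False
    as_printed: str | None = None

    def residual(self) -> sp.Expr:
        f = self.closed_form
        return sp.diff(f, r)**2 - (b1 * f**2 + b2 * f**3 + b3 * f**4)


@dataclass(frozen=True)
class GG2Case:
    """Closed form for H = G'/G² with H' = τ + κH²."""

    case: str
    closed_form: sp.Expr
    validity: tuple
    source_eq: int = 0
    corrected: bool = False
    as_printed: str | None = None

    def residual(self) -> sp.Expr:
        return sp.diff(self.closed_form, r) - tau - kappa * self.closed_form**2


@dataclass(frozen=True)
class TanhCase:
    """Closed form for ς with ς' = κ + ς²."""

    case: str
    closed_form: sp.Expr
    validity: tuple
    source_eq: int = 0

    def residual(self) -> sp.Expr:
        return sp.diff(self.closed_form, r) - kappa - self.closed_form**2


def aux_library(b1v=b1, b2v=b2, b3v=b3, branches=(1, -1)):
    """The sixteen solution families of the quartic auxiliary equation.

    Both signs of every ± are expanded (``branch``).  Forms marked
    ``corrected`` differ from the reference tables, which contain
    typographical slips (unsquared denominators, sech for csch, a
    degenerate rational form); the stored forms are the ones that
    satisfy the defining relation under the stated conditions.
    """
    sq = sp.sqrt
    h = sq(b1) * r / 2          # half-argument, b1 > 0 families
    w = sq(b1) * r
    ht = sq(-b1) * r / 2        # trigonometric families, b1 < 0
    wt = sq(-b1) * r
    entries = []

    def add(eq, family, form_of_pm, validity, corrected=False, printed=None,
            own_branches=None):
        for pm in (own_branches if own_branches is not None else branches):
            entries.append(AuxLibraryEntry(
                eq, family, sp.sympify(form_of_pm(pm)), tuple(validity),
                branch=pm, corrected=corrected, as_printed=printed))

    add(33, "hyperbolic",
        lambda pm: -b1 * b2 * sp.sech(h)**2
        / (b2**2 - b1 * b3 * (1 + pm * sp.tanh(h))**2),
        [b1 > 0], corrected=True,
        printed="-b1*b2*sech(h)^2/(b2^2 - b1*b3*(1 +- tanh(h)))")
    add(34, "hyperbolic",
        lambda pm: b1 * b2 * sp.csch(h)**2
        / (b2**2 - b1 * b3 * (1 + pm * sp.coth(h))**2),
        [b1 > 0], corrected=True,
        printed="b1*b2*csch(h)^2/(b2^2 - b1*b3*(1 +- coth(h)))")
    add(35, "hyperbolic",
        lambda pm: 2 * b1 * sp.sech(w) / (pm * sp.sqrt(zeta)
                                          - b2 * sp.sech(w)),
        [b1 > 0, zeta > 0], corrected=True,
        printed="2*b1*sech(w)^2/(+-sqrt(zeta) - b2*sech(w))")
    add(36, "hyperbolic",
        lambda pm: 2 * b1 * sp.csch(w) / (pm * sp.sqrt(-zeta)
                                          - b2 * sp.csch(w)),
        [b1 > 0, zeta < 0], corrected=True,
        printed="2*b1*csch(w)^2/(+-sqrt(-zeta) - b2*sech(w)), zeta>0")
    add(37, "hyperbolic",
        lambda pm: -b1 * sp.sech(h)**2
        / (b2 + pm * 2 * sp.sqrt(b1 * b3) * sp.tanh(h)),
        [b1 > 0, b3 > 0])
    add(38, "hyperbolic",
        lambda pm: b1 * sp.csch(h)**2
        / (b2 + pm * 2 * sp.sqrt(b1 * b3) * sp.coth(h)),
        [b1 > 0, b3 > 0])
    add(39, "hyperbolic",
        lambda pm: -(b1 / b2) * (1 + pm * sp.tanh(h)),
        [b1 > 0, sp.Eq(zeta, 0)])
    add(40, "hyperbolic",
        lambda pm: -(b1 / b2) * (1 + pm * sp.coth(h)),
        [b1 > 0, sp.Eq(zeta, 0)])
    add(41, "trigonometric",
        lambda pm: -b1 * sp.sec(ht)**2
        / (b2 + pm * 2 * sp.sqrt(-b1 * b3) * sp.tan(ht)),
        [b1 < 0, b3 > 0])
    add(42, "trigonometric",
        lambda pm: -b1 * sp.csc(ht)**2
        / (b2 + pm * 2 * sp.sqrt(-b1 * b3) * sp.cot(ht)),
        [b1 < 0, b3 > 0])
    add(43, "trigonometric",
        lambda pm: 2 * b1 * sp.sec(wt) / (pm * sp.sqrt(zeta)
                                          - b2 * sp.sec(wt)),
        [b1 < 0, zeta > 0], corrected=True,
        printed="2*b1*sec(wt)^2/(+-sqrt(zeta) - b2*sec(wt))")
    add(44, "trigonometric",
        lambda pm: 2 * b1 * sp.csc(wt) / (pm * sp.sqrt(zeta)
                                          - b2 * sp.csc(wt)),
        [b1 < 0, zeta > 0], corrected=True,
        printed="2*b1*csc(wt)^2/(+-sqrt(zeta) - b2*sec(wt))")
    add(45, "exponential",
        lambda pm: 4 * b1 * sp.exp(pm * w)
        / ((sp.exp(pm * w) - b2)**2 - 4 * b1 * b3),
        [b1 > 0])
    add(46, "exponential",
        lambda pm: pm * 4 * b1 * sp.exp(pm * w)
        / (1 - 4 * b1 * b3 * sp.exp(pm * 2 * w)),
        [b1 > 0, sp.Eq(b2, 0)])
    add(47, "rational",
        lambda pm: 4 * b2 / (b2**2 * r**2 - 4 * b3),
        [sp.Eq(b1, 0)], corrected=True, own_branches=(1,),
        printed="+-b1*b2/(b2^2*r^2 - b1*b3), degenerate (== 0) at b1=0")
    add(48, "rational",
        lambda pm: pm / (sp.sqrt(b3) * r),
        [sp.Eq(b1, 0), sp.Eq(b2, 0), b3 > 0])
    if (b1v, b2v, b3v) != (b1, b2, b3):
        subs = {b1: b1v, b2: b2v, b3: b3v}
        entries = [replace(e, closed_form=e.closed_form.subs(subs),
                           validity=tuple(v.subs(subs) for v in e.validity))
                   for e in entries]
    return entries


def gg2_library(tau_v=tau, kappa_v=kappa):
    """The three sign cases of the ratio-variable Riccati equation.

    All three printed forms fail H' = τ + κH² and are stored corrected:
    Case 1 needs prefactor −√(κτ)/κ; Case 2 is a pure tanh/coth ratio
    with argument √|κτ|ρ; the consistent third case is τ = 0 (not κ = 0)
    with H = −A₁/(κ(A₁ρ + B₁)).
    """
    th = sp.sqrt(kappa * tau) * r
    n = sp.sqrt(sp.Abs(kappa * tau))
    cases = [
        GG2Case("kt_pos",
                -(sp.sqrt(kappa * tau) / kappa)
                * (A1 * sp.cos(th) + B1 * sp.sin(th))
                / (A1 * sp.sin(th) - B1 * sp.cos(th)),
                (kappa * tau > 0,), source_eq=51, corrected=True,
                as_printed="sqrt(k/t)*(A1*cos+B1*sin)/(A1*sin-B1*cos)"),
        GG2Case("kt_neg",
                (tau / n) * (A1 * sp.sinh(n * r) + B1 * sp.cosh(n * r))
                / (A1 * sp.cosh(n * r) + B1 * sp.sinh(n * r)),
                (kappa * tau < 0,), source_eq=52, corrected=True,
                as_printed="-sqrt(|kt|)/t + sqrt(|kt|)/2*(A1*sinh(2nr)+"
                           "B1*cosh(2nr))/(A1*cosh(2nr)+B1*sinh(2nr))"),
        GG2Case("tau_zero",
                -A1 / (kappa * (A1 * r + B1)),
                (sp.Eq(tau, 0), sp.Ne(kappa, 0)), source_eq=53,
                corrected=True,
                as_printed="-A1/(t*(A1*r+B1)) with k=0 (inconsistent)"),
    ]
    if (tau_v, kappa_v) != (tau, kappa):
        subs = {tau: tau_v, kappa: kappa_v}
        cases = [replace(c, closed_form=c.closed_form.subs(subs),
                         validity=tuple(v.subs(subs) for v in c.validity))
                 for c in cases]
    return cases


#: printed (G'/G²) case forms, used when reproducing the printed families
GG2_PRINTED = {
    "kt_pos": sp.sqrt(kappa / tau)
    * (A1 * sp.cos(sp.sqrt(kappa * tau) * r)
       + B1 * sp.sin(sp.sqrt(kappa * tau) * r))
    / (A1 * sp.sin(sp.sqrt(kappa * tau) * r)
       - B1 * sp.cos(sp.sqrt(kappa * tau) * r)),
    "kt_neg": -sp.sqrt(sp.Abs(kappa * tau)) / tau
    + sp.sqrt(sp.Abs(kappa * tau)) / 2
    * (A1 * sp.sinh(2 * sp.sqrt(sp.Abs(kappa * tau)) * r)
       + B1 * sp.cosh(2 * sp.sqrt(sp.Abs(kappa * tau)) * r))
    / (A1 * sp.cosh(2 * sp.sqrt(sp.Abs(kappa * tau)) * r)
       + B1 * sp.sinh(2 * sp.sqrt(sp.Abs(kappa * tau)) * r)),
    "tau_zero": -A1 / (tau * (A1 * r + B1)),
}


def tanh_library(kappa_v=kappa):
    """The five case forms of ς' = κ + ς² (all printed forms are sound)."""
    sqn = sp.sqrt(-kappa)
    sqp = sp.sqrt(kappa)
    cases = [
        TanhCase("k_neg_tanh", -sqn * sp.tanh(sqn * r), (kappa < 0,), 56),
        TanhCase("k_neg_coth", -sqn * sp.coth(sqn * r), (kappa < 0,), 57),
        TanhCase("k_zero", -1 / r, (sp.Eq(kappa, 0),), 58),
        TanhCase("k_pos_tan", sqp * sp.tan(sqp * r), (kappa > 0,), 59),
        TanhCase("k_pos_cot", -sqp * sp.cot(sqp * r), (kappa > 0,), 60),
    ]
    if kappa_v != kappa:
        cases = [replace(c, closed_form=c.closed_form.subs(kappa, kappa_v),
                         validity=tuple(v.subs(kappa, kappa_v)
                                        for v in c.validity))
                 for c in cases]
    return cases


# --------------------------------------------------------------------------
# reference ("paper") parameter sets

a0, a1 = sp.symbols("a0 a1")
_b1t = sp.Symbol("b1")   # tanh-method reciprocal coefficient


def paper_sets(method: str | None = None):
    """The printed parameter sets, verbatim, with provenance ``paper``.

    Every ± is enumerated through ``branch=(pm,)`` applied consistently
    within a set (∓ takes −pm).  Residuals of these sets against their
    generating systems are *reported*, never assumed zero.
    """
    out = []
    Raux = sp.sqrt(9 * b2**4 - 32 * b1 * b2**2 * b3)
    W = sp.sqrt(b2**2 * (9 * b2**2 - 32 * b1 * b3) * d_sym**2)
    for pm in (1, -1):
        alpha0 = (9 * b2**2 + pm * 3 * Raux - 32 * b1 * b3) \
            / (18 * b2**2 - 64 * b1 * b3)
        out.append(ParameterSet(
            {a0: alpha0,
             a1: pm * 4 * b3 * Raux / (9 * b2**3 - 32 * b1 * b2 * b3),
             gamma_sym: 9 * b2**2 * d_sym / (2 * b3) - 16 * b1 * d_sym,
             sigma_sym: alpha0},
            "aux", "paper", 62, (pm,),
            notes="alpha0 and sigma are printed as identical expressions"))
        out.append(ParameterSet(
            {a0: sp.S.One,
             a1: (pm * W + 3 * b2**2 * d_sym) / (4 * b1 * b2 * d_sym),
             gamma_sym: (-pm * 3 * W + 9 * b2**2 * d_sym
                         - 16 * b1 * b3 * d_sym) / (4 * b3),
             sigma_sym: (-pm * W - 9 * b2**2 * d_sym
                         + 32 * b1 * b3 * d_sym) / (16 * b1 * b3 * d_sym)},
            "aux", "paper", 79, (pm,)))
        out.append(ParameterSet(
            {a0: sp.S.Zero,
             a1: (pm * W - 3 * b2**2 * d_sym) / (4 * b1 * b2 * d_sym),
             gamma_sym: (pm * 3 * W + 9 * b2**2 * d_sym
                         - 16 * b1 * b3 * d_sym) / (4 * b3),
             sigma_sym: (-pm * 3 * W + 9 * b2**2 * d_sym
                         - 16 * b1 * b3 * d_sym) / (16 * b1 * b3 * d_sym)},
            "aux", "paper", 96, (pm,)))
    s = sigma_sym
    disc = s**2 + 6 * s + 1
    out.append(ParameterSet(
        {a0: (s + 1) / 2,
         a1: -2 * kappa / (gamma_sym * s + gamma_sym),
         d_sym: 2 / (gamma_sym * (s + 1)**2),
         tau: -gamma_sym**2 * (s + 1)**2 * disc / (16 * kappa)},
        "gg2", "paper", 114))
    X = sp.sqrt(disc)
    out.append(ParameterSet(
        {a0: (-X + s + 1) / 4,
         a1: kappa * (3 * X - s - 1) / (gamma_sym * (2 * s**2 + 13 * s + 2)),
         d_sym: (5 * s**2 + (28 - 3 * X) * s - 3 * X + 5)
         / (gamma_sym * (2 * s**2 + 13 * s + 2)**2),
         tau: gamma_sym**2 * (-s**4 + (9 * X - 40) * s**2
                              + 3 * (3 * X - 4) * s) / (32 * kappa)
         + gamma_sym**2 * (X + (X - 12) * s**3 - 1) / (32 * kappa)},
        "gg2", "paper", 118,
        notes="tau spans two display lines; grouping is ambiguous "
              "(both parts read as divided by 32*kappa)"))
    out.append(ParameterSet(
        {a0: (s + 1) / 2, a1: -2 * d_sym * (s + 1), _b1t: sp.S.Zero,
         kappa: -disc / (16 * d_sym**2 * (s + 1)**2),
         gamma_sym: 1 / (d_sym * (s + 1)**2)},
        "tanh", "paper", 123))
    out.append(ParameterSet(
        {a0: (s + 1) / 2, a1: -2 * d_sym * (s + 1),
         _b1t: -disc / (32 * d_sym * s + 32 * d_sym),
         kappa: -disc / (64 * d_sym**2 * (s + 1)**2),
         gamma_sym: 1 / (d_sym * (s + 1)**2)},
        "tanh", "paper", 130))
    if method is not None:
        out = [p for p in out if p.method == method]
    return out


# --------------------------------------------------------------------------
# assembly and classification

@dataclass
class ClosedFormSolution:
    """Explicit solution u(r) with travelling-variable definition."""

    expression: sp.Expr
    r_definition: sp.Expr | None
    conditions: tuple = ()
    method: str = ""
    set_source: int | None = None
    provenance: str = "derived"
    branch: tuple = ()
    source_eq: int | None = None        # printed family equation, if any
    entry_eq: int | None = None         # library entry it came from
    vacuous: bool | None = None
    classification: str | None = None
    parameter_set: "ParameterSet | None" = None

    def lifted(self) -> sp.Expr:
        """The solution as an explicit field of the original variables."""
        if self.r_definition is None:
            return self.expression
        return self.expression.subs(r, self.r_definition)


# printed family numbering: (set source eq, entry/case eq) -> family eq
_FAMILY_EQ = {}
for _i, _eq in enumerate(range(33, 49)):
    _FAMILY_EQ[(62, _eq)] = 63 + _i
    _FAMILY_EQ[(79, _eq)] = 80 + _i
    _FAMILY_EQ[(96, _eq)] = 97 + _i
for _i, _eq in enumerate(range(51, 54)):
    _FAMILY_EQ[(114, _eq)] = 115 + _i
    _FAMILY_EQ[(118, _eq)] = 119 + _i
for _i, _eq in enumerate(range(56, 61)):
    _FAMILY_EQ[(123, _eq)] = 125 + _i
    _FAMILY_EQ[(130, _eq)] = 132 + _i


def _condition_status(conditions, assignments):
    """True / False / None for a condition set under set constraints."""
    verdicts = []
    for cond in conditions:
        c = cond.subs(assignments) if assignments else cond
        if sp.count_ops(c) <= 40:
            c = sp.simplify(c)
        if c in (sp.true, True):
            verdicts.append(True)
        elif c in (sp.false, False):
            verdicts.append(False)
        else:
            verdicts.append(_probe_condition(c))
    if any(v is False for v in verdicts):
        return False
    if all(v is True for v in verdicts):
        return True
    return None


def _probe_condition(cond):
    """Sample a relational over plausible parameter values."""
    syms = sorted(cond.free_symbols, key=str)
    grid = [0.3, 0.7, 1.4]
    results = []
    import itertools as it

    for combo in it.product(grid, repeat=len(syms)):
        try:
            v = cond.subs(dict(zip(syms, combo)))
        except Exception:
            continue
        if v in (sp.true, True):
            results.append(True)
        elif v in (sp.false, False):
            results.append(False)
    if results and all(results):
        return True
    if results and not any(results):
        return False
    return None


def assemble_solutions(pset: ParameterSet, entries, r_definition=None,
                       use_printed: bool | None = None):
    """Substitute each library entry into the truncated ansatz.

    Validity conditions are the union of the entry's conditions and the
    set's induced constraints; incompatible combinations are emitted
    with ``vacuous=True`` rather than dropped.  For paper-provenance
    sets the printed case forms are used (``use_printed`` overrides), so
    the assembled expressions string-match the printed families.
    """
    if use_printed is None:
        use_printed = pset.provenance == "paper"
    N = 1
    ansatz, _ = expansion_ansatz(pset.method, N)
    sols = []
    for entry in entries:
        form = entry.closed_form
        if use_printed and isinstance(entry, GG2Case):
            form = GG2_PRINTED[entry.case]
        expr = ansatz.subs(S, form)
        expr = expr.subs(pset.assignments)
        conds = tuple(entry.validity)
        status = _condition_status(conds, pset.assignments)
        sols.append(ClosedFormSolution(
            expression=expr,
            r_definition=r_definition,
            conditions=conds,
            method=pset.method,
            set_source=pset.source_eq,
            provenance=pset.provenance,
            branch=pset.branch + (getattr(entry, "branch", 0),),
            source_eq=_FAMILY_EQ.get((pset.source_eq,
                                      getattr(entry, "source_eq", None))),
            entry_eq=getattr(entry, "source_eq", None),
            vacuous=(status is False),
            parameter_set=pset,
        ))
    return sols


# --------------------------------------------------------------------------
# profile classification

def classify_solution(sol, params=None, window=(-10.0, 10.0), n=4001,
                      pole_threshold=1e6):
    """Label a fully numeric profile by shape analysis on a window.

    kink / anti-kink: bounded monotone front, increasing / decreasing in
    r; bright / dark: localized hump / dip over a flat background;
    periodic: repeating structure (poles allowed: tan/sec families);
    singular: isolated non-repeating poles; rational: poles with
    algebraic (power-law) tails; constant / unclassified otherwise.
    """
    expr = sol.expression if isinstance(sol, ClosedFormSolution) else sol
    expr = sp.sympify(expr)
    if params:
        expr = expr.subs(params)
    free = expr.free_symbols - {r}
    if free:
        raise ValueError(f"profile still has free parameters: {free}")
    f = sp.lambdify(r, expr, modules=["numpy"])
    rr = np.linspace(window[0], window[1], n)
    with np.errstate(all="ignore"):
        vals = np.asarray(f(rr + 0j), dtype=complex)
    if vals.shape != rr.shape:
        vals = np.full(rr.shape, complex(vals))
    re, im = vals.real, vals.imag
    finite = np.isfinite(re) & (np.abs(re) < pole_threshold)
    if finite.any():
        # adaptive pole cut: values far beyond the typical magnitude
        med = np.median(np.abs(re[finite]))
        cut = min(pole_threshold, max(100.0, 50.0 * max(med, 1e-3)))
        finite &= np.abs(re) < cut
    scale = np.nanmax(np.abs(re[finite])) if finite.any() else 1.0
    real_ok = np.abs(im) < 1e-8 * max(1.0, scale)
    if (finite & ~real_ok).sum() > 0.1 * n:
        return "unclassified"
    has_poles = (~finite).any()
    if has_poles:
        return _classify_with_poles(rr, re, finite)
    return _classify_bounded(rr, re)


def _pole_positions(rr, finite):
    idx = np.where(~finite)[0]
    if idx.size == 0:
        return np.array([])
    groups = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
    return np.array([rr[g].mean() for g in groups])


def _classify_with_poles(rr, re, finite):
    poles = _pole_positions(rr, finite)
    if poles.size >= 3:
        gaps = np.diff(poles)
        if gaps.size and np.allclose(gaps, gaps.mean(), rtol=0.05):
            return "periodic"
    # tail decay: algebraic tails mean a rational profile
    half = rr > max(poles.max() if poles.size else 0, 0) + 1.0
    if half.sum() > 100:
        rt, vt = rr[half], re[half]
        tail = np.abs(vt - vt[-1])
        mask = tail > 1e-12
        if mask.sum() > 50:
            # compare decay across a doubling of distance
            r1 = rt[mask][len(rt[mask]) // 3]
            r2 = min(2 * r1, rt[mask][-2])
            if r2 > r1:
                v1 = np.interp(r1, rt, tail)
                v2 = np.interp(r2, rt, tail)
                if v2 > 0 and v1 > 0:
                    slope = math.log(v1 / v2) / math.log(r2 / r1)
                    if 0.3 < slope < 4.0:
                        return "rational"
    return "singular"


def _classify_bounded(rr, re):
    span = re.max() - re.min()
    scale = max(1.0, np.abs(re).max())
    if span < 1e-9 * scale:
        return "constant"
    k = max(len(rr) // 20, 5)
    left, right = re[:k].mean(), re[-k:].mean()
    dv = np.diff(re)
    tol = 1e-9 * scale
    monotone_up = (dv >= -tol).all()
    monotone_dn = (dv <= tol).all()
    if abs(right - left) > 0.2 * span:
        if monotone_up:
            return "kink"
        if monotone_dn:
            return "anti-kink"
    # localized structures over a common background
    background = (left + right) / 2
    if abs(left - right) < 0.05 * span:
        dev = re - background
        imax, imin = np.argmax(dev), np.argmin(dev)
        if dev[imax] > 4 * abs(dev[imin]) and rr[0] < rr[imax] < rr[-1]:
            return "bright"
        if abs(dev[imin]) > 4 * dev[imax] and rr[0] < rr[imin] < rr[-1]:
            return "dark"
        return _periodic_or_unclassified(rr, re, span)
    return _periodic_or_unclassified(rr, re, span)


def _periodic_or_unclassified(rr, re, span):
    g = re - re.mean()
    ac = np.correlate(g, g, mode="full")[len(g) - 1:]
    ac /= ac[0]
    # first strong autocorrelation revival away from zero lag
    min_lag = 20
    peaks = [i for i in range(min_lag, len(ac) - 1)
             if ac[i] > 0.6 and ac[i] >= ac[i - 1] and ac[i] >= ac[i + 1]]
    if peaks and peaks[0] < len(g) // 2:
        return "periodic"
    return "unclassified"


# --------------------------------------------------------------------------
# library verification

def library_residual_status(entry, seed: int = 0) -> str:
    """Three-valued check of an entry's defining-relation residual.

    Equality conditions (e.g. ζ = 0) are substituted exactly; inequality
    conditions restrict the numeric sampling domain.
    """
    res = entry.residual()
    inequalities = []
    eq_subs = {}
    prefer = [b3, b2, b1, tau, kappa]
    for c in entry.validity:
        if isinstance(c, sp.Eq):
            target = next((sym for sym in prefer if c.free_symbols >= {sym}
                           and sym not in eq_subs), None)
            if target is None:
                continue
            sols = sp.solve(c, target)
            if sols:
                eq_subs[target] = sols[0]
        elif isinstance(c, sp.Ne):
            continue
        else:
            inequalities.append(c)
    res = res.subs(eq_subs, simultaneous=True)
    inequalities = [c.subs(eq_subs, simultaneous=True)
                    for c in inequalities]
    inequalities = [c for c in inequalities if c not in (sp.true, True)]
    return zero_status(res, seed=seed, conditions=inequalities,
                       simplify=False)
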