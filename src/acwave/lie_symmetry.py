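"""Lie point symmetries of the bistable Allen-Cahn equation.

A point vector field

    X = chi1*d/dt + chi2*d/dx + chi3*d/dy + phi*d/dM,

with coefficients depending on (t, x, y, M), generates a symmetry when
its second prolongation annihilates the equation's residual on the
solution manifold.  The prolongation coefficients follow the
total-derivative recursion

    phi^v  = D_v(phi) - M_t D_v(chi1) - M_x D_v(chi2) - M_y D_v(chi3),
    phi^vv = D_v(phi^v) - M_tv D_v(chi1) - M_xv D_v(chi2) - M_yv D_v(chi3).

Splitting the invariance condition by monomials in the independent jet
coordinates gives the (overdetermined, linear) determining equations;
for generic d, gamma, sigma their general solution is

    chi1 = C3,  chi2 = -C1*y + C4,  chi3 = C1*x + C2,  phi = 0,

a four-dimensional algebra spanned by the two space translations, the
time translation and the rotation y*d/dx - x*d/dy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import sympy as sp

from .jets import (M, M_t, M_tx, M_ty, M_x, M_xx, M_y, M_yy, jet,
                   jet_symbols, t, x, y, total_derivative)
from .model import BACModel

__all__ = [
    "VectorFieldGen",
    "ProlongedField",
    "CommutatorTable",
    "prolong2",
    "determining_equations",
    "solve_determining",
    "generator_basis",
    "commutator",
    "commutator_table",
]

_POINT_VARS = (t, x, y, M)


@dataclass(frozen=True)
class VectorFieldGen:
    """Point vector field chi1*dt + chi2*dx + chi3*dy + phi*dM."""

    chi1: sp.Expr
    chi2: sp.Expr
    chi3: sp.Expr
    phi: sp.Expr
    label: str = field(default="", compare=False)

    def __post_init__(self):
        for name in ("chi1", "chi2", "chi3", "phi"):
            e = sp.sympify(getattr(self, name))
            object.__setattr__(self, name, e)
            if jet_symbols(e) not in ([], [M]) and set(jet_symbols(e)) - {M}:
                raise ValueError(
                    f"point field component {name} depends on derivatives: {e}"
                )

    @property
    def components(self):
        return (self.chi1, self.chi2, self.chi3, self.phi)

    def apply(self, f: sp.Expr) -> sp.Expr:
        """Action on a function of (t, x, y, M) as a derivation."""
        c1, c2, c3, p = self.components
        return sp.expand(
            c1 * sp.diff(f, t) + c2 * sp.diff(f, x)
            + c3 * sp.diff(f, y) + p * sp.diff(f, M)
        )

    def is_zero(self) -> bool:
        return all(sp.simplify(c) == 0 for c in self.components)

    def __add__(self, other):
        return VectorFieldGen(*(a + b for a, b in
                                zip(self.components, other.components)))

    def __mul__(self, scalar):
        return VectorFieldGen(*(sp.expand(scalar * c) for c in self.components))

    __rmul__ = __mul__

    def __str__(self):
        names = ("d/dt", "d/dx", "d/dy", "d/dM")
        parts = [f"({sp.sstr(c)})*{n}" for c, n in zip(self.components, names)
                 if c != 0]
        return " + ".join(parts) if parts else "0"


@dataclass(frozen=True)
class ProlongedField:
    """Second prolongation coefficients of a point vector field."""

    base: VectorFieldGen
    phi_t: sp.Expr
    phi_x: sp.Expr
    phi_y: sp.Expr
    phi_xx: sp.Expr
    phi_yy: sp.Expr

    def apply(self, jet_expr: sp.Expr) -> sp.Expr:
        """Action of X^(2) on an expression over the second-order jet."""
        vf = self.base
        out = (
            vf.chi1 * sp.diff(jet_expr, t)
            + vf.chi2 * sp.diff(jet_expr, x)
            + vf.chi3 * sp.diff(jet_expr, y)
            + vf.phi * sp.diff(jet_expr, M)
            + self.phi_t * sp.diff(jet_expr, M_t)
            + self.phi_x * sp.diff(jet_expr, M_x)
            + self.phi_y * sp.diff(jet_expr, M_y)
            + self.phi_xx * sp.diff(jet_expr, M_xx)
            + self.phi_yy * sp.diff(jet_expr, M_yy)
        )
        return sp.expand(out)


def prolong2(vf: VectorFieldGen) -> ProlongedField:
    """Second prolongation via the total-derivative recursion."""
    c1, c2, c3, p = vf.components

    def first(v):
        return sp.expand(
            total_derivative(p, v)
            - M_t * total_derivative(c1, v)
            - M_x * total_derivative(c2, v)
            - M_y * total_derivative(c3, v)
        )

    phi_t, phi_x, phi_y = first(t), first(x), first(y)

    def second(phi_v, v, idx):
        return sp.expand(
            total_derivative(phi_v, v)
            - jet("t" + idx) * total_derivative(c1, v)
            - jet("x" + idx) * total_derivative(c2, v)
            - jet("y" + idx) * total_derivative(c3, v)
        )

    return ProlongedField(
        base=vf,
        phi_t=phi_t,
        phi_x=phi_x,
        phi_y=phi_y,
        phi_xx=second(phi_x, x, "x"),
        phi_yy=second(phi_y, y, "y"),
    )


def unknown_ansatz() -> VectorFieldGen:
    """Fully general point-field ansatz with undetermined functions."""
    f = [sp.Function(n)(t, x, y, M) for n in ("chi1", "chi2", "chi3", "phi")]
    return VectorFieldGen(*f, label="ansatz")


def _on_solution_manifold(model: BACModel, expr: sp.Expr) -> sp.Expr:
    """Eliminate M_t, M_tx, M_ty using the equation and its x/y derivatives."""
    F = sp.expand(model.d * (M_xx + M_yy) - model.reaction)
    subs = {
        M_tx: total_derivative(F, x),
        M_ty: total_derivative(F, y),
        M_t: F,
    }
    return sp.expand(expr.subs(subs, simultaneous=True))


def invariance_condition(model: BACModel, vf: VectorFieldGen) -> sp.Expr:
    """X^(2)(residual) restricted to the solution manifold."""
    return _on_solution_manifold(model, prolong2(vf).apply(model.residual_form))


def _split_by_jets(expr: sp.Expr, keep=(M,)):
    """Coefficients of monomials in all jet coordinates except ``keep``."""
    gens = sorted((s for s in jet_symbols(expr) if s not in keep), key=str)
    if not gens:
        return [expr] if expr != 0 else []
    poly = sp.Poly(expr, *gens, domain="EX")
    return [sp.expand(c) for c in poly.coeffs()]


def determining_equations(model: BACModel, ansatz: VectorFieldGen | None = None):
    """Overdetermined linear system for the infinitesimals.

    Applies the prolonged ansatz to the residual, eliminates M_t (and
    its spatial derivatives) via the equation, and splits by monomials
    in the remaining independent jet coordinates.
    """
    if ansatz is None:
        ansatz = unknown_ansatz()
    cond = invariance_condition(model, ansatz)
    eqs = _split_by_jets(cond)
    # deduplicate up to constant multiples
    seen, out = set(), []
    for e in eqs:
        key = sp.factor(e)
        if key == 0:
            continue
        if key not in seen and -key not in seen:
            seen.add(key)
            out.append(e)
    return out


@dataclass
class GeneralSymmetry:
    """General solution of the determining equations."""

    field: VectorFieldGen              # components contain free constants
    free_constants: list               # sympy symbols C1..Cn
    branch_conditions: list            # parameter factors assumed nonzero
    ansatz_degree: int

    @property
    def dimension(self) -> int:
        return len(self.free_constants)

    def basis(self) -> list[VectorFieldGen]:
        fields = []
        for c in self.free_constants:
            comps = [sp.expand(comp.subs([(c, 1)] + [(o, 0) for o in
                     self.free_constants if o != c]))
                     for comp in self.field.components]
            fields.append(VectorFieldGen(*comps, label=str(c)))
        return fields


def _poly_ansatz(degree: int):
    """Polynomial ansatz components and their coefficient symbols."""
    monoms = []
    for exps in itertools.product(range(degree + 1), repeat=4):
        if sum(exps) <= degree:
            monoms.append(t**exps[0] * x**exps[1] * y**exps[2] * M**exps[3])
    comps, coeffs = [], []
    for name in ("a", "b", "c", "p"):
        cs = sp.symbols(f"{name}0:{len(monoms)}")
        coeffs.extend(cs)
        comps.append(sum(c * m for c, m in zip(cs, monoms)))
    return VectorFieldGen(*comps), list(coeffs)


def _gauss_nullspace(A: sp.Matrix, params):
    """Row-reduce over the rational-function field in ``params``.

    Returns (rank, branch_factors): elimination records every
    parameter-dependent pivot factor assumed nonzero, so special
    parameter values that could enlarge the solution space are surfaced
    rather than silently merged.
    """
    A = A.copy()
    rows, cols = A.shape
    branch = set()
    pr = 0
    for c in range(cols):
        piv = None
        for r in range(pr, rows):
            if sp.simplify(A[r, c]) != 0:
                piv = r
                break
        if piv is None:
            continue
        if piv != pr:
            A.row_swap(piv, pr)
        pv = sp.factor(A[pr, c])
        for fac in sp.Mul.make_args(pv):
            base = fac.as_base_exp()[0]
            if base.free_symbols & set(params):
                branch.add(base)
        A[pr, :] = sp.expand(A[pr, :] / pv)
        for r in range(rows):
            if r != pr and A[r, c] != 0:
                A[r, :] = sp.expand(A[r, :] - A[r, c] * A[pr, :])
        pr += 1
        if pr == rows:
            break
    return pr, sorted(branch, key=str)


def solve_determining(system, model: BACModel | None = None, degree: int = 2,
                      check_stabilisation: bool = False) -> GeneralSymmetry:
    """General solution of the determining equations.

    The unknown infinitesimals are expanded in a polynomial basis in
    (t, x, y, M) of total degree ``degree``; the determining equations
    then reduce to a linear system for the coefficients, solved over the
    rational-function field in the model parameters.  With
    ``check_stabilisation`` the dimension is re-computed at
    ``degree + 1`` and must not change.
    """
    if model is None:
        from .model import make_bac_model

        model = make_bac_model()
    params = [s for s in (model.d, model.gamma, model.sigma)
              if isinstance(s, sp.Symbol)]

    def solve_at(deg):
        ansatz, coeffs = _poly_ansatz(deg)
        funcs = unknown_ansatz()
        sub = dict(zip(funcs.components, ansatz.components))
        lin = []
        for eq in system:
            e = eq
            # replace unknown functions (and their derivatives) by the ansatz
            for f_un, f_poly in sub.items():
                e = e.replace(
                    lambda a: isinstance(a, sp.Derivative)
                    and a.expr == f_un,
                    lambda a: sp.diff(f_poly, *a.variable_count),
                )
                e = e.subs(f_un, f_poly)
            e = sp.expand(e)
            poly = sp.Poly(e, t, x, y, M, domain="EX")
            lin.extend(poly.coeffs())
        A, _ = sp.linear_eq_to_matrix(lin, coeffs)
        rank, branch = _gauss_nullspace(A, params)
        n_free = len(coeffs) - rank
        # general solution via linsolve
        sol = sp.linsolve(lin, coeffs)
        if not sol:
            raise RuntimeError("determining system inconsistent")
        vec = list(sol)[0]
        free = sorted({s for comp in vec for s in comp.free_symbols
                       if s in set(coeffs)}, key=str)
        assign = dict(zip(coeffs, vec))
        consts = sp.symbols(f"C1:{len(free) + 1}")
        rename = dict(zip(free, consts))
        comps = [sp.expand(c.subs(assign).subs(rename))
                 for c in ansatz.components]
        return GeneralSymmetry(VectorFieldGen(*comps), list(consts),
                               branch, deg), n_free

    gen, n_free = solve_at(degree)
    if n_free != gen.dimension:  # pragma: no cover - consistency guard
        raise RuntimeError("rank bookkeeping mismatch")
    if check_stabilisation:
        gen_hi, _ = solve_at(degree + 1)
        if gen_hi.dimension != gen.dimension:
            raise RuntimeError(
                f"symmetry dimension not stabilised: {gen.dimension} at "
                f"degree {degree} vs {gen_hi.dimension} at {degree + 1}"
            )
    return gen


def generator_basis() -> list[VectorFieldGen]:
    """Canonical basis: d/dt, d/dx, d/dy, y*d/dx - x*d/dy."""
    return [
        VectorFieldGen(1, 0, 0, 0, label="X1"),
        VectorFieldGen(0, 1, 0, 0, label="X2"),
        VectorFieldGen(0, 0, 1, 0, label="X3"),
        VectorFieldGen(0, y, -x, 0, label="X4"),
    ]


def commutator(a: VectorFieldGen, b: VectorFieldGen) -> VectorFieldGen:
    """Lie bracket [a, b] = a(b) - b(a) on point vector fields."""
    comps = [sp.expand(a.apply(bc) - b.apply(ac))
             for ac, bc in zip(a.components, b.components)]
    return VectorFieldGen(*comps)


class ClosureError(RuntimeError):
    def __init__(self, i, j, field):
        self.pair = (i, j)
        super().__init__(
            f"bracket [X{i + 1}, X{j + 1}] = {field} is outside the span "
            "of the basis"
        )


@dataclass
class CommutatorTable:
    """n x n table of structure coordinates in the given basis."""

    basis: list
    coords: list  # coords[i][j] = tuple of coefficients in the basis

    def entry(self, i, j) -> VectorFieldGen:
        coeffs = self.coords[i][j]
        out = VectorFieldGen(0, 0, 0, 0)
        for c, b in zip(coeffs, self.basis):
            if c != 0:
                out = out + c * b
        return out

    def is_antisymmetric(self) -> bool:
        n = len(self.basis)
        return all(
            all(self.coords[i][j][k] == -self.coords[j][i][k]
                for k in range(n))
            for i in range(n) for j in range(n)
        )

    def jacobi_holds(self) -> bool:
        n = len(self.basis)
        for i, j, k in itertools.product(range(n), repeat=3):
            Xi, Xj, Xk = (self.basis[m] for m in (i, j, k))
            total = (
                commutator(Xi, commutator(Xj, Xk))
                + commutator(Xj, commutator(Xk, Xi))
                + commutator(Xk, commutator(Xi, Xj))
            )
            if not total.is_zero():
                return False
        return True


def _in_span(field: VectorFieldGen, basis) -> tuple | None:
    """Coordinates of ``field`` in ``basis`` or None if outside the span."""
    cs = sp.symbols(f"_s0:{len(basis)}")
    combo = VectorFieldGen(0, 0, 0, 0)
    for c, b in zip(cs, basis):
        combo = combo + c * b
    eqs = []
    for fc, cc in zip(field.components, combo.components):
        diff = sp.expand(fc - cc)
        if diff == 0:
            continue
        poly = sp.Poly(diff, t, x, y, M, domain="EX")
        eqs.extend(poly.coeffs())
    sol = sp.linsolve(eqs, list(cs))
    if not sol:
        return None
    vec = list(sol)[0]
    if any(s.free_symbols & set(cs) for s in vec):
        vec = [v.subs(dict.fromkeys(cs, 0)) for v in vec]
    return tuple(sp.nsimplify(v) for v in vec)


def commutator_table(basis=None) -> CommutatorTable:
    """Full bracket table with antisymmetry/closure checks."""
    if basis is None:
        basis = generator_basis()
    n = len(basis)
    coords = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            br = commutator(basis[i], basis[j])
            c = _in_span(br, basis)
            if c is None:
                raise ClosureError(i, j, br)
            coords[i][j] = c
    table = CommutatorTable(basis=basis, coords=coords)
    if not table.is_antisymmetric():  # pragma: no cover - sanity guard
        raise RuntimeError("bracket table not antisymmetric")
    return table
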