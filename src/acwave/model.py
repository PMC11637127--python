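"""The bistable Allen-Cahn biofilm model.

The density M(t, x, y) of microbes on a rectangular surface evolves by

    M_t = d*(M_xx + M_yy) - gamma*M*(M - 1)*(M - sigma),

a reaction-diffusion equation with quartic (double-well) potential:
``d`` is the diffusion coefficient, ``gamma`` the growth rate and
``sigma in [0, 1]`` the survival rate separating the two stable uniform
states 0 (extinct) and 1 (saturated biofilm).  Expanded, the reaction is
``gamma*M**3 - gamma*(1+sigma)*M**2 + gamma*sigma*M``, so the residual
form used throughout is

    M_t - d*M_xx - d*M_yy + gamma*M**3 - gamma*(1+sigma)*M**2 + gamma*sigma*M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .jets import M, M_t, M_x, M_xx, M_y, M_yy, jet_symbols, t, x, y

__all__ = ["BACModel", "make_bac_model", "pde_residual", "DEFAULT_SYMBOLS"]

#: symbolic defaults, shared so reductions/solvers agree on the symbols
DEFAULT_SYMBOLS = sp.symbols("d gamma sigma", positive=True)


class ModelValidationError(ValueError):
    """Raised for parameter values incompatible with the model."""


@dataclass(frozen=True)
class BACModel:
    """Bistable Allen-Cahn equation with parameters d, gamma, sigma.

    Parameters may be positive numbers or sympy symbols; downstream
    solvers work symbolically and specialise late (the expansion-method
    parameter sets constrain d, gamma, sigma themselves).
    """

    d: sp.Expr
    gamma: sp.Expr
    sigma: sp.Expr
    #: optional plotting rectangle [e, g] x [n, m]
    domain: tuple | None = field(default=None, compare=False)

    def __post_init__(self):
        for name in ("d", "gamma", "sigma"):
            object.__setattr__(self, name, sp.sympify(getattr(self, name)))
        for name in ("d", "gamma"):
            v = getattr(self, name)
            if v.is_number and not v.is_positive:
                raise ModelValidationError(f"{name} must be positive, got {v}")
        s = self.sigma
        if s.is_number and not (0 <= float(s) <= 1):
            warnings.warn(
                f"sigma={s} outside [0, 1]; solver parameter sets may "
                "constrain sigma outside the biological range",
                stacklevel=3,
            )

    @property
    def reaction(self) -> sp.Expr:
        """Reaction polynomial gamma*M*(M-1)*(M-sigma), expanded in M."""
        return sp.expand(self.gamma * M * (M - 1) * (M - self.sigma))

    def reaction_of(self, u: sp.Expr) -> sp.Expr:
        return self.reaction.subs(M, u)

    @property
    def residual_form(self) -> sp.Expr:
        """LHS of the equation on jet coordinates (zero on solutions)."""
        return M_t - self.d * M_xx - self.d * M_yy + self.reaction

    def steady_states(self):
        """The spatially uniform equilibria: 0, sigma, 1."""
        return (sp.S.Zero, self.sigma, sp.S.One)

    def subs_params(self, d=None, gamma=None, sigma=None) -> "BACModel":
        return BACModel(
            d if d is not None else self.d,
            gamma if gamma is not None else self.gamma,
            sigma if sigma is not None else self.sigma,
            domain=self.domain,
        )


def make_bac_model(d=None, gamma=None, sigma=None, domain=None) -> BACModel:
    """Build a :class:`BACModel`; symbolic parameters by default."""
    dd, gg, ss = DEFAULT_SYMBOLS
    return BACModel(
        dd if d is None else d,
        gg if gamma is None else gamma,
        ss if sigma is None else sigma,
        domain=domain,
    )


_ALLOWED = {t, x, y}


def pde_residual(model: BACModel, field_expr):
    """Residual of the equation for a field given as an expression or grid.

    Symbolic mode: ``field_expr`` is an expression in (t, x, y) (or any
    subset; missing derivatives vanish).  Grid mode: a dict with keys
    ``M``, ``M_t``, ``M_xx`` (and optionally ``M_yy``) holding numpy
    arrays of pre-computed derivative stencils.
    """
    if isinstance(field_expr, dict):
        g, s = float(model.gamma), float(model.sigma)
        d = float(model.d)
        Mv = np.asarray(field_expr["M"], dtype=float)
        Mt = np.asarray(field_expr["M_t"], dtype=float)
        Mxx = np.asarray(field_expr["M_xx"], dtype=float)
        Myy = np.asarray(field_expr.get("M_yy", np.zeros_like(Mv)), dtype=float)
        return Mt - d * Mxx - d * Myy + g * Mv * (Mv - 1.0) * (Mv - s)

    f = sp.sympify(field_expr)
    # canonicalise coordinate symbols that arrived via bare sympify
    f = f.subs({sym: {"t": t, "x": x, "y": y}[sym.name]
                for sym in f.free_symbols
                if sym.name in ("t", "x", "y") and sym not in _ALLOWED})
    # scalar symbols beyond (t, x, y) are treated as free parameters, but
    # an unknown function of anything other than (t, x, y) is a mistake
    for fn in f.atoms(sp.core.function.AppliedUndef):
        if set(fn.args) - _ALLOWED:
            raise ValueError(
                f"field references unknown variables through {fn}")
    if f.has(M) or jet_symbols(f):
        # jet expression: derivatives are total derivatives on jet space
        from .jets import total_derivative as Dj

        return sp.expand(model.residual_form.subs(
            {M_t: Dj(f, t), M_xx: Dj(Dj(f, x), x),
             M_yy: Dj(Dj(f, y), y), M: f}, simultaneous=True))
    res = (
        sp.diff(f, t)
        - model.d * sp.diff(f, x, 2)
        - model.d * sp.diff(f, y, 2)
        + model.reaction_of(f)
    )
    return sp.expand(res)


def total_diff(f, idx):
    """Ordinary derivative of an explicit field f(t,x,y) by index string."""
    out = f
    for v in idx:
        out = sp.diff(out, {"t": t, "x": x, "y": y}[v])
    return out
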