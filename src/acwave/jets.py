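"""Second-order jet space over (t, x, y) with unknown M.

The symmetry machinery works on expressions over a finite jet space:
the base coordinates ``t, x, y``, the unknown ``M`` and symbols for its
partial derivatives ``M_t, M_x, ..., M_xxx, ...`` up to a configurable
order.  Derivative symbols are named by their sorted multi-index, so
``M_tx`` and ``M_xt`` are the same coordinate (mixed partials commute).

Total derivatives act by the chain rule through every jet coordinate:

    D_v(F) = dF/dv + sum_J (dF/dM_J) * M_{J+v}

which is the recursion used to prolong a point vector field.
"""

from __future__ import annotations

import sympy as sp

#: base coordinates
t, x, y = sp.symbols("t x y", real=True)

_BASE_ORDER = {"t": 0, "x": 1, "y": 2}

MAX_ORDER = 4


def jet(index: str = "") -> sp.Symbol:
    """Jet coordinate for the multi-index ``index`` (e.g. ``"xx"``, ``"tx"``).

    The empty index is the unknown itself.  Indices are canonicalised by
    sorting, so ``jet("xt") is jet("tx")``.
    """
    idx = "".join(sorted(index, key=_BASE_ORDER.__getitem__))
    if len(idx) > MAX_ORDER:
        raise ValueError(f"jet order {len(idx)} exceeds MAX_ORDER={MAX_ORDER}")
    return sp.Symbol("M" if not idx else f"M_{idx}", real=True)


#: the unknown and its low-order jets, for convenience
M = jet()
M_t, M_x, M_y = jet("t"), jet("x"), jet("y")
M_xx, M_yy, M_xy = jet("xx"), jet("yy"), jet("xy")
M_tt, M_tx, M_ty = jet("tt"), jet("tx"), jet("ty")


def _all_jets(max_order: int = MAX_ORDER):
    out = {}
    indices = [""]
    for _ in range(max_order):
        indices = [i + v for i in indices for v in "txy"]
        for i in indices:
            s = jet(i)
            out[s] = "".join(sorted(i, key=_BASE_ORDER.__getitem__))
    return out


_JET_INDEX = _all_jets()  # symbol -> canonical index string


def jet_symbols(expr: sp.Expr):
    """Jet coordinates (including M itself) occurring in ``expr``."""
    return [s for s in expr.free_symbols if s == M or s in _JET_INDEX]


def total_derivative(expr: sp.Expr, var) -> sp.Expr:
    """Total derivative D_v on the jet space, v in {t, x, y}.

    Chain rule through the unknown and all of its derivative symbols;
    e.g. ``D_x(M_x**2) = 2*M_x*M_xx`` and ``D_t(t*M) = M + t*M_t``.
    """
    v = {t: "t", x: "x", y: "y", "t": "t", "x": "x", "y": "y"}[var]
    base = {"t": t, "x": x, "y": y}[v]
    expr = sp.sympify(expr)
    out = sp.diff(expr, base)
    out += sp.diff(expr, M) * jet(v)
    for s in expr.free_symbols:
        idx = _JET_INDEX.get(s)
        if idx:
            out += sp.diff(expr, s) * jet(idx + v)
    return sp.expand(out)
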