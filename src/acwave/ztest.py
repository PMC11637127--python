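"""Three-valued symbolic zero testing.

Canonical simplification first (skipped for very large expressions);
when simplification stalls, the expression is sampled at seeded random
points and compared against the magnitude of its top-level terms,
giving one of ``zero``, ``nonzero`` or ``undecided``.  Points too close
to a singularity (any term blowing up) are rejected.
"""

from __future__ import annotations

import random

import numpy as np
import sympy as sp

__all__ = ["zero_status", "numeric_max_abs"]

DEFAULT_TOL = 1e-10
N_SAMPLES = 25
SIMPLIFY_OPS_LIMIT = 300


def _try_simplify(expr):
    for f in (sp.expand, sp.radsimp, lambda e: sp.simplify(sp.together(e))):
        if sp.count_ops(expr) > SIMPLIFY_OPS_LIMIT:
            return expr
        try:
            new = f(expr)
        except Exception:
            continue
        if new == 0:
            return sp.S.Zero
        if sp.count_ops(new) <= sp.count_ops(expr):
            expr = new
    return expr


#: default sampling intervals by symbol name; sigma is a survival rate
#: in [0, 1], so identities are probed on its biological range
NAMED_RANGES = {"sigma": (0.05, 0.95)}


def _sample(sym, rng, ranges):
    lo, hi = ranges.get(sym, NAMED_RANGES.get(sym.name, (None, None)))
    if lo is None:
        lo, hi = (0.1, 2.5) if sym.is_positive else (-2.0, 2.0)
    v = rng.uniform(lo, hi)
    # keep away from zero where sign is unconstrained
    if lo < 0 < hi and abs(v) < 0.05:
        v = 0.05 if v >= 0 else -0.05
    return v


def _term_functions(expr, syms):
    terms = sp.Add.make_args(expr)
    funcs = []
    for tm in terms:
        try:
            funcs.append(sp.lambdify(syms, tm, modules=["numpy"]))
        except Exception:
            return None
    return funcs


def _finite(z) -> bool:
    return bool(np.isfinite(z.real)) and bool(np.isfinite(z.imag))


def _sample_values(funcs, syms, rng, ranges, n, huge=1e10, predicates=()):
    """Yield (value, scale) pairs at admissible sample points."""
    got = 0
    attempts = 0
    while got < n and attempts < 40 * n:
        attempts += 1
        real_point = [_sample(s, rng, ranges) for s in syms]
        try:
            if not all(bool(p(*real_point)) for p in predicates):
                continue
        except Exception:
            continue
        point = [complex(v) for v in real_point]
        try:
            with np.errstate(all="ignore"):
                vals = [complex(f(*point)) for f in funcs]
        except Exception:
            continue
        if not all(_finite(v) for v in vals):
            continue
        scale = max([abs(v) for v in vals] + [1.0])
        if scale > huge:
            continue  # too close to a singularity to be informative
        got += 1
        yield sum(vals), scale


def zero_status(expr, seed: int = 0, tol: float = DEFAULT_TOL,
                ranges: dict | None = None, n: int = N_SAMPLES,
                conditions=(), simplify: bool = True) -> str:
    """Decide whether ``expr`` vanishes identically.

    ``ranges`` optionally maps free symbols to (lo, hi) sampling
    intervals; ``conditions`` is an iterable of sympy relationals that
    sample points must satisfy (validity conditions such as b1 > 0 or
    zeta > 0).  ``simplify=False`` skips straight to numeric sampling
    (useful for large transcendental residuals).
    """
    expr = sp.sympify(expr)
    if expr.is_zero:
        return "zero"
    simp = _try_simplify(expr) if simplify else expr
    if simp.is_zero:
        return "zero"
    syms = sorted(simp.free_symbols, key=str)
    if not syms:
        try:
            return "zero" if abs(complex(simp)) < tol else "nonzero"
        except Exception:
            return "undecided"
    funcs = _term_functions(simp, syms)
    if funcs is None:
        return "undecided"
    rng = random.Random(seed)
    preds = _predicate_functions(conditions, syms)
    if preds is None:
        return "undecided"
    hits = misses = 0
    for val, scale in _sample_values(funcs, syms, rng, ranges or {}, n,
                                     predicates=preds):
        if abs(val) <= tol * scale:
            hits += 1
        else:
            misses += 1
    if hits + misses < max(3, n // 5):
        return "undecided"
    if misses == 0:
        return "zero"
    if hits == 0 or misses > hits:
        return "nonzero"
    return "undecided"


def numeric_max_abs(expr, seed: int = 0, ranges: dict | None = None,
                    n: int = N_SAMPLES, conditions=()) -> float | None:
    """Max |expr| over seeded admissible sample points."""
    expr = sp.sympify(expr)
    syms = sorted(expr.free_symbols, key=str)
    if not syms:
        try:
            return abs(complex(expr))
        except Exception:
            return None
    funcs = _term_functions(expr, syms)
    if funcs is None:
        return None
    rng = random.Random(seed)
    preds = _predicate_functions(conditions, syms)
    if preds is None:
        return None
    best = None
    for val, _ in _sample_values(funcs, syms, rng, ranges or {}, n,
                                 predicates=preds):
        best = abs(val) if best is None else max(best, abs(val))
    return best


def _predicate_functions(conditions, syms):
    preds = []
    for c in conditions:
        import sympy as _sp

        if isinstance(c, _sp.Eq):
            continue  # equalities must be substituted by the caller
        try:
            preds.append(sp.lambdify(syms, c, modules=["numpy"]))
        except Exception:
            return None
    return preds
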