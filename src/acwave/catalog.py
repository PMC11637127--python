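"""Catalog assembly shared by the CLI and the reporting layer."""

from __future__ import annotations

import pandas as pd
import sympy as sp

from . import wave_solvers as W
from .jets import t as t_sym, x as x_sym, y as y_sym
from .model import BACModel
from .reductions import case_reduction, reduce_plane_wave

#: travelling/similarity variable used by each method's printed chain
R_DEFINITION = {
    "aux": x_sym**2 + 2 * x_sym - 2 * y_sym + y_sym**2,
    "gg2": t_sym - y_sym,
    "tanh": t_sym - x_sym - y_sym,
}

DEFAULT_ODE = {
    "aux": lambda m: case_reduction(m, 1)[2].reduced,
    "gg2": lambda m: reduce_plane_wave(m, (0, 1)),
    "tanh": lambda m: reduce_plane_wave(m, (1, 1)),
}

LIBRARIES = {
    "aux": W.aux_library,
    "gg2": W.gg2_library,
    "tanh": W.tanh_library,
}


def build_catalog(model: BACModel, method: str, ode=None,
                  include_paper: bool = False, seed: int = 0,
                  classify_at: dict | None = None) -> dict:
    """Solve one method end to end and package the results.

    Returns ``{"json": ..., "summary": DataFrame, "sets": [...],
    "solutions": [...]}``.
    """
    if ode is None:
        ode = DEFAULT_ODE[method](model)
    N = W.homogeneous_balance(ode, method)
    system = W.build_algebraic_system(ode, method, N)
    sets = W.solve_parameter_sets(system, seed=seed)
    all_sets = list(sets)
    if include_paper:
        for ps in W.paper_sets(method):
            statuses = [W.zero_status(e.subs(ps.assignments), seed=seed,
                                      simplify=False)
                        for e in system.equations]
            ps.residual_status = ("zero" if all(s == "zero" for s in statuses)
                                  else "nonzero" if "nonzero" in statuses
                                  else "undecided")
            all_sets.append(ps)
    entries = LIBRARIES[method]()
    solutions = []
    for ps in all_sets:
        solutions.extend(W.assemble_solutions(ps, entries,
                                              R_DEFINITION[method]))
    rows = []
    for sol in solutions:
        label = None
        if classify_at:
            try:
                label = W.classify_solution(sol, classify_at)
            except (ValueError, TypeError):
                label = None
        rows.append({
            "method": method,
            "set_eq": sol.set_source,
            "provenance": sol.provenance,
            "branch": "/".join(map(str, sol.branch)),
            "entry_eq": sol.entry_eq,
            "family_eq": sol.source_eq,
            "vacuous": sol.vacuous,
            "classification": label,
        })
    summary = pd.DataFrame(rows)
    payload = {
        "method": method,
        "ode": str(ode),
        "balance_N": N,
        "degenerate_branches": sets.degenerate_count,
        "spurious_branches": sets.spurious_count,
        "sets": [{
            "assignments": {str(k): str(v) for k, v in ps.assignments.items()},
            "provenance": ps.provenance,
            "source_eq": ps.source_eq,
            "branch": list(ps.branch),
            "residual_status": ps.residual_status,
            "notes": ps.notes,
        } for ps in all_sets],
        "n_solutions": len(solutions),
    }
    return {"json": payload, "summary": summary, "sets": all_sets,
            "solutions": solutions}


def verify_all(model: BACModel, seed: int = 0):
    """Residual reports of every derived set's kink solution per method."""
    rows = []
    for method in W.METHODS:
        ode = DEFAULT_ODE[method](model)
        N = W.homogeneous_balance(ode, method)
        system = W.build_algebraic_system(ode, method, N)
        for ps in W.solve_parameter_sets(system, seed=seed):
            statuses = [W.zero_status(e.subs(ps.assignments), seed=seed)
                        for e in system.equations]
            rows.append({
                "method": method,
                "set": str(ps),
                "symbolic_status": "zero" if all(s == "zero"
                                                 for s in statuses)
                else ("nonzero" if "nonzero" in statuses else "undecided"),
            })
    table = pd.DataFrame(rows)
    return table, rows


def full_catalog(model: BACModel, seed: int = 0) -> dict:
    """Catalog of all three methods plus preset classifications."""
    out = {}
    for method in W.METHODS:
        out[method] = build_catalog(model, method, include_paper=True,
                                    seed=seed)["json"]["sets"]
    from .cli_viz import figure_presets

    presets = []
    for p in figure_presets():
        presets.append({"fig": p.fig, "expected": p.expected,
                        "classification": W.classify_solution(p.profile)})
    out["presets"] = presets
    return out
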