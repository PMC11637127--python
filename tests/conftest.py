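import pytest
import sympy as sp

from acwave.model import make_bac_model
from acwave import reductions as R
from acwave import wave_solvers as W


@pytest.fixture(scope="session")
def model():
    """Fully symbolic model (d, gamma, sigma)."""
    return make_bac_model()


@pytest.fixture(scope="session")
def ode13(model):
    """As-printed constant-coefficient steady ODE (aux-method target)."""
    return R.case_reduction(model, 1)[2].reduced


@pytest.fixture(scope="session")
def ode18(model):
    return R.reduce_plane_wave(model, (0, 1))


@pytest.fixture(scope="session")
def ode23(model):
    return R.reduce_plane_wave(model, (1, 0))


@pytest.fixture(scope="session")
def ode28(model):
    return R.reduce_plane_wave(model, (1, 1))


def _sets(ode, method, seed=0):
    system = W.build_algebraic_system(
        ode, method, W.homogeneous_balance(ode, method))
    return system, W.solve_parameter_sets(system, seed=seed)


@pytest.fixture(scope="session")
def aux_solution(ode13):
    return _sets(ode13, "aux")


@pytest.fixture(scope="session")
def gg2_solution(ode18):
    return _sets(ode18, "gg2")


@pytest.fixture(scope="session")
def tanh_solution(ode28):
    return _sets(ode28, "tanh")


def find_set(sets, conds):
    """First parameter set whose assignments match ``conds`` exactly."""
    for ps in sets:
        if all(sp.simplify(ps.get(sym, sp.nan) - val) == 0
               for sym, val in conds.items()):
            return ps
    raise AssertionError(f"no set matching {conds}")
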