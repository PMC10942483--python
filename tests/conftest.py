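import numpy as np
import pytest

from pinndiff import (
    BoundaryCondition,
    ForwardProblem,
    ScalarField2D,
    cell_centered_coords,
    simulate,
)
from pinndiff.forward import disc_initial_condition


@pytest.fixture(scope="session")
def constant_d_series():
    """Small forward run with constant D = 0.1, blob IC, zero-flux walls."""
    n = 48
    x = cell_centered_coords(n)
    d_field = ScalarField2D(np.full((n, n), 0.1), x, x)
    ic = disc_initial_condition(x, x)
    problem = ForwardProblem(d_field, ic, BoundaryCondition.zero_flux(), nt=25)
    return simulate(problem)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
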