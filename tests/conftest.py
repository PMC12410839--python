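"""Shared fixtures: tiny grids, parameter sets, and 1-3 cell states."""

import numpy as np
import pytest

from cellstrand.dynamics import CellRecord
from cellstrand.energetics import ModelParams, interface_width
from cellstrand.fields import GridSpec, PhaseFieldState, tanh_disk


@pytest.fixture
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture
def soft_params() -> ModelParams:
    """A softer, faster-relaxing parameter set for small dynamical tests."""
    return ModelParams(alpha=20.0, K=4.66, lam=800.0, g=60.0, g_wall=60.0,
                       omega=0.0, kappa=0.0)


@pytest.fixture
def periodic_grid() -> GridSpec:
    return GridSpec(48, 48, 1.0, boundary_x="periodic", boundary_y="periodic")


def make_cell_state(grid, params, centers, radius_factor=0.95, wall=None):
    d = interface_width(params)
    phi = np.stack(
        [tanh_disk(grid, c, radius_factor * params.R, d) for c in centers]
    )
    if wall is None:
        wall = np.zeros(grid.shape)
    state = PhaseFieldState(phi, wall, grid)
    cells = [CellRecord(id=i, theta=0.0, com=tuple(c)) for i, c in enumerate(centers)]
    return state, cells


@pytest.fixture
def single_cell(periodic_grid, soft_params):
    return make_cell_state(periodic_grid, soft_params, [(24.0, 24.0)])


@pytest.fixture
def two_cells(periodic_grid, soft_params):
    sep = 2 * soft_params.R - 1.0
    c = 24.0
    return make_cell_state(
        periodic_grid, soft_params, [(c - sep / 2, c), (c + sep / 2, c)]
    )
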