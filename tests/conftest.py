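import math

import numpy as np
import pytest

import spinlrf as s


DEFAULT_ANGULAR = 110  # fast default for unit tests; acceptance uses 302


@pytest.fixture(scope="session")
def closed_shell_toy():
    return s.build_two_site_toy(0.0)


@pytest.fixture(scope="session")
def bs_toy():
    """Broken-symmetry two-site toy at theta = pi/8 (T = cos pi/4)."""
    return s.build_two_site_toy(math.pi / 8)


@pytest.fixture(scope="session")
def toy_grid_ao():
    """Grid and AO values shared by response tests (theta-independent)."""
    toy = s.build_two_site_toy(0.0)
    grid = s.assemble_ws_grid(toy.geometry, 50, DEFAULT_ANGULAR)
    ao = s.eval_basis(toy.shells, toy.geometry, grid.points)
    return grid, ao


@pytest.fixture(scope="session")
def chain4():
    return s.make_chain_toy(4)


def make_grid(system, n_radial=50, n_angular=DEFAULT_ANGULAR):
    grid = s.assemble_ws_grid(system.geometry, n_radial, n_angular)
    ao = s.eval_basis(system.shells, system.geometry, grid.points)
    return grid, ao
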