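"""Shared fixtures: small synthetic structures and simulated reflection data.

Everything is generated programmatically with fixed seeds so the suite needs
no data files and is bit-reproducible.
"""

import numpy as np
import pytest

from shiftfield import UnitCell, make_toy_structure, simulate_observations
from shiftfield.synthetic import SimulationSpec


@pytest.fixture(scope="session")
def helix10():
    """10-residue polyalanine helix in a P1 cell (40 backbone atoms)."""
    return make_toy_structure("poly_ala_helix", 10, cell_padding=8.0)


@pytest.fixture(scope="session")
def helix10_sym():
    """10-residue helix with P 21 21 21 symmetry (origin-pinning fixture)."""
    return make_toy_structure("poly_ala_helix", 10, cell_padding=10.0,
                              spacegroup="P 21 21 21")


@pytest.fixture(scope="session")
def helix10_refl(helix10):
    """Error-free 3 Å data simulated from the P1 helix."""
    return simulate_observations(helix10, SimulationSpec(d_min=3.0, seed=11))


@pytest.fixture(scope="session")
def helix10_sym_refl(helix10_sym):
    """Error-free 3 Å data simulated from the P212121 helix."""
    return simulate_observations(helix10_sym, SimulationSpec(d_min=3.0, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def cubic_cell():
    return UnitCell(20.0, 20.0, 20.0)
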