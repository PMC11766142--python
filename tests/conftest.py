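import numpy as np
import pytest

from dpslattice import DPS_CRYSTAL_CELL, UnitCell

#: experimental interplanar distances of the intracellular-crystal rings (A)
EXP_D = (69.6, 54.5, 45.0, 34.4)


@pytest.fixture
def dps_cell() -> UnitCell:
    return DPS_CRYSTAL_CELL


def random_valid_cell(rng: np.random.Generator, lo: float = 5.0, hi: float = 15.0) -> UnitCell:
    """Rejection-sample a geometrically realizable triclinic cell."""
    while True:
        a, b, c = rng.uniform(lo, hi, 3)
        al, be, ga = rng.uniform(50.0, 130.0, 3)
        try:
            return UnitCell(a, b, c, al, be, ga)
        except ValueError:
            continue


def brute_force_basis(cell: UnitCell) -> np.ndarray:
    """Independent lattice-vector construction (a along x, b in xy-plane)."""
    al, be, ga = np.radians(cell.angles)
    av = np.array([cell.a, 0.0, 0.0])
    bv = cell.b * np.array([np.cos(ga), np.sin(ga), 0.0])
    cx = np.cos(be)
    cy = (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
    cz = np.sqrt(1.0 - cx * cx - cy * cy)
    cv = cell.c * np.array([cx, cy, cz])
    return np.array([av, bv, cv])
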