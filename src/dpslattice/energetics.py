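"""Scalar analyses behind the trimer assignment.

Three small, exact computations:

* thermodynamic-integration bookkeeping — the subunit binding free energy of
  a trimer is the difference between the ghost-to-bound and ghost-to-solvated
  Gibbs energies, ``ddG = dG_bound - dG_solvation``, with independent
  quadrature error propagation;
* the shifted Lennard-Jones 12-6 potential used by the coarse-grained water
  model (the ordinary/antifreeze water distinction lives entirely in sigma);
* rigid-volume monomer capacity of the toroidal particle seen in the
  crystal — how many protein monomers fit into a 70 x 70 x 44 A particle —
  under a bounding-box, cylinder, or cylinder-minus-cavity volume model.

Energies are kJ/mol; LJ distances are nm (the force-field convention);
particle dimensions are Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "TIRecord",
    "LJParams",
    "ParticleDims",
    "binding_delta_g",
    "lj_potential",
    "monomer_capacity",
    "DPS_TI_RECORDS",
]


@dataclass(frozen=True)
class TIRecord:
    """Ghost-to-solvated and ghost-to-bound Gibbs energies (kJ/mol)."""

    dG_solvation: float
    err_solvation: float
    dG_bound: float
    err_bound: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.err_solvation < 0 or self.err_bound < 0:
            raise ValueError("errors must be >= 0")


#: Published slow-growth TI results for the Dps subunit: solvation (dG1) and
#: the bound states in the Dps-type (dG2) and ferritin-like (dG3) trimers.
DPS_TI_RECORDS = {
    "dps_pore": TIRecord(-1787.7, 27.7, -1903.16, 32.05, label="Dps-type pore trimer"),
    "ferritin_pore": TIRecord(
        -1787.7, 27.7, -1973.68, 27.08, label="ferritin-like pore trimer"
    ),
}


def binding_delta_g(record: TIRecord) -> tuple[float, float]:
    """Subunit binding free energy ddG = dG_bound - dG_solvation (kJ/mol).

    Returns (ddG, error) with the error propagated in quadrature assuming
    independent uncertainties on the two legs.
    """
    ddg = record.dG_bound - record.dG_solvation
    err = math.hypot(record.err_bound, record.err_solvation)
    return ddg, err


@dataclass(frozen=True)
class LJParams:
    """Lennard-Jones 12-6 parameters: epsilon kJ/mol, sigma nm."""

    epsilon: float
    sigma: float
    shift: bool = False
    r_cutoff: float = 1.2  # nm, the van der Waals cutoff of the CG simulations

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be > 0")
        if self.shift and self.r_cutoff <= 0:
            raise ValueError("cutoff must be > 0 for the shifted form")


def lj_potential(r: float, params: LJParams) -> float:
    """U(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6], optionally cutoff-shifted.

    With ``shift`` the value at the cutoff is subtracted so U(r_cutoff) = 0.
    """
    if r <= 0:
        raise ValueError("r must be > 0")

    def plain(x: float) -> float:
        s6 = (params.sigma / x) ** 6
        return 4.0 * params.epsilon * (s6 * s6 - s6)

    u = plain(r)
    if params.shift:
        u -= plain(params.r_cutoff)
    return u


@dataclass(frozen=True)
class ParticleDims:
    """Toroidal-particle and monomer dimensions in Angstrom."""

    particle_diameter: float = 70.0
    particle_height: float = 44.0
    monomer_box: tuple[float, float, float] = (58.0, 25.0, 35.0)
    cavity_diameter: Optional[float] = None

    def __post_init__(self) -> None:
        if self.particle_diameter <= 0 or self.particle_height <= 0:
            raise ValueError("particle dimensions must be > 0")
        if any(e <= 0 for e in self.monomer_box):
            raise ValueError("monomer box edges must be > 0")
        if self.cavity_diameter is not None and not (
            0 < self.cavity_diameter < self.particle_diameter
        ):
            raise ValueError("cavity diameter must lie in (0, particle diameter)")


_CAPACITY_MODES = ("box", "cylinder", "cylinder_minus_cavity")


def monomer_capacity(dims: ParticleDims, mode: str = "cylinder") -> int:
    """How many monomers fit in the particle by rigid volume division.

    box: d x d x h bounding box; cylinder: pi (d/2)^2 h; cylinder_minus_cavity
    additionally subtracts the central cavity cylinder.  Returns
    floor(particle volume / monomer volume) — a capacity bound, not a packing.
    """
    if mode not in _CAPACITY_MODES:
        raise ValueError(f"mode must be one of {_CAPACITY_MODES}")
    d, h = dims.particle_diameter, dims.particle_height
    if mode == "box":
        v = d * d * h
    else:
        v = math.pi * (d / 2.0) ** 2 * h
        if mode == "cylinder_minus_cavity":
            if dims.cavity_diameter is None:
                raise ValueError("cylinder_minus_cavity requires a cavity diameter")
            v -= math.pi * (dims.cavity_diameter / 2.0) ** 2 * h
    v_mono = math.prod(dims.monomer_box)
    return int(v // v_mono)
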