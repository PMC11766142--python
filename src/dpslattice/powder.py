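"""Powder X-ray pattern simulation for a model crystal.

Structure factors are computed directly from point/Gaussian scatterers (no
map FFT): ``F(hkl) = sum_j w_j exp(-q^2 s_j^2 / 2) exp(2 pi i (h,k,l).x_j)``
with fractional coordinates ``x_j`` and per-site Gaussian widths ``s_j``
acting as a simple isotropic form factor.  Peaks are placed at the Bragg
angle of each Friedel-canonical reflection, given multiplicity 2 (the
Friedel pair — P1 has no further symmetry), and broadened with the Gaussian
whose FWHM follows the Scherrer relation ``K lambda / (L cos theta)`` for a
crystallite of linear size ``L``.  The per-angle intensities of all peaks
are summed to the 1D pattern, which can then be compared against an
experimental d-spacing list with :func:`match_peaks`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cell import Reflection, UnitCell, bragg_convert, enumerate_reflections
from .synthetic import Curve1D, ScattererSet

__all__ = [
    "PowderPattern",
    "PeakMatchReport",
    "structure_factor",
    "size_broadening",
    "simulate_powder_pattern",
    "match_peaks",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class PowderPattern:
    """Simulated 1D powder curve plus full provenance."""

    curve: Curve1D
    cell: UnitCell
    crystallite_size: float
    wavelength: float
    reflections: list[Reflection] = field(default_factory=list)

    @property
    def peak_d(self) -> np.ndarray:
        return np.array([r.d for r in self.reflections])

    @property
    def peak_two_theta(self) -> np.ndarray:
        return np.array(
            [
                bragg_convert(r.d, "d_angstrom", "two_theta_deg", self.wavelength)
                for r in self.reflections
            ]
        )


@dataclass
class PeakMatchReport:
    """Greedy matching of experimental d values to model d values."""

    pairs: list[dict]  # experimental_d, model_d, rel_diff
    matched: int
    n_experimental: int
    tolerance: float

    @property
    def all_matched(self) -> bool:
        return self.matched == self.n_experimental


def structure_factor(scatterers: ScattererSet, cell: UnitCell, hkl) -> float:
    """|F(hkl)|^2 of a scatterer set in the given cell.

    Sites may lie anywhere (a crystal block spanning many cells is fine:
    translating a site by a lattice vector multiplies its phase by unity
    only for integer hkl, which is the case here).  Sites farther than ten
    cells from the origin trigger a warning, not an error.
    """
    h = np.asarray(hkl, dtype=float)
    if h.shape != (3,) or np.all(h == 0):
        raise ValueError("hkl must be a nonzero integer triple")
    B = cell.basis()
    frac = scatterers.sites @ np.linalg.inv(B)
    if np.any(np.abs(frac) > 10.0):
        import warnings

        warnings.warn("scatterer more than 10 cells from the origin", stacklevel=2)
    d = cell.d_spacing(hkl)
    q = 2.0 * math.pi / d
    damp = np.exp(-0.5 * (q * scatterers.widths) ** 2)
    phase = np.exp(2j * math.pi * (frac @ h))
    F = np.sum(scatterers.weights * damp * phase)
    return float(np.abs(F) ** 2)


def size_broadening(
    two_theta_deg: float,
    wavelength: float,
    crystallite_size: float,
    shape_constant: float = 0.9,
) -> float:
    """Gaussian sigma (degrees) of the Scherrer size-broadened peak.

    FWHM (radians) = K lambda / (L cos theta); sigma = FWHM / (2 sqrt(2 ln 2)).
    """
    if crystallite_size <= 0:
        raise ValueError("crystallite size must be > 0")
    if not 0.0 < two_theta_deg < 180.0:
        raise ValueError("2theta must lie in (0, 180) degrees")
    theta = math.radians(two_theta_deg / 2.0)
    if math.cos(theta) < 1e-9:
        raise ValueError("Scherrer formula diverges as theta approaches 90 degrees")
    fwhm_rad = shape_constant * wavelength / (crystallite_size * math.cos(theta))
    return math.degrees(fwhm_rad) * _FWHM_TO_SIGMA


def simulate_powder_pattern(
    cell: UnitCell,
    scatterers: ScattererSet,
    wavelength: float = 1.542,
    crystallite_size: float = 2000.0,
    d_min: float = 30.0,
    grid: np.ndarray | None = None,
    shape_constant: float = 0.9,
    lorentz: bool = False,
) -> PowderPattern:
    """Sum of size-broadened Gaussian peaks over all reflections with d >= d_min.

    Each canonical reflection contributes area ``2 |F|^2`` (Friedel
    multiplicity); the optional Lorentz factor ``1/(sin theta sin 2theta)``
    is off by default since peak positions, not intensities, are the
    quantity compared with experiment.
    """
    refl = enumerate_reflections(cell, d_min)
    if not refl:
        raise ValueError(f"no reflection with d >= {d_min} A")
    tth = np.array(
        [bragg_convert(r.d, "d_angstrom", "two_theta_deg", wavelength) for r in refl]
    )
    if grid is None:
        hi = tth.max() + 0.3
        grid = np.linspace(max(tth.min() - 0.3, 0.01), hi, int(hi / 0.002))
    grid = np.asarray(grid, dtype=float)
    y = np.zeros_like(grid)
    clipped = 0.0
    for r, t in zip(refl, tth):
        r.weight = structure_factor(scatterers, cell, r.hkl)
        area = 2.0 * r.weight
        if lorentz:
            th = math.radians(t / 2.0)
            area *= 1.0 / (math.sin(th) * math.sin(2 * th))
        sig = size_broadening(t, wavelength, crystallite_size, shape_constant)
        if t - 3 * sig < grid[0] or t + 3 * sig > grid[-1]:
            clipped += area
        y += area / (sig * math.sqrt(2 * math.pi)) * np.exp(-0.5 * ((grid - t) / sig) ** 2)
    if clipped > 0:
        import warnings

        warnings.warn(
            f"grid truncates peaks carrying total area {clipped:.3g}", stacklevel=2
        )
    curve = Curve1D(x=grid, y=y, x_kind="two_theta_deg", wavelength=wavelength)
    return PowderPattern(
        curve=curve,
        cell=cell,
        crystallite_size=crystallite_size,
        wavelength=wavelength,
        reflections=refl,
    )


def match_peaks(
    model_d,
    experimental_d,
    rel_tolerance: float = 0.05,
) -> PeakMatchReport:
    """Greedy best-pair matching of experimental to model d-spacings.

    Candidate pairs are ranked by relative difference; each experimental and
    each model value is used at most once; pairs beyond the tolerance are
    not matched.
    """
    model_d = list(np.atleast_1d(np.asarray(model_d, dtype=float)))
    exp_d = list(np.atleast_1d(np.asarray(experimental_d, dtype=float)))
    if not 0.0 < rel_tolerance < 0.5:
        raise ValueError("rel_tolerance must lie in (0, 0.5)")
    if len(exp_d) == 0:
        raise ValueError("experimental peak list is empty")
    cands = sorted(
        (
            (abs(m - e) / e, ei, mi)
            for ei, e in enumerate(exp_d)
            for mi, m in enumerate(model_d)
        ),
        key=lambda t: t[0],
    )
    used_e: set[int] = set()
    used_m: set[int] = set()
    pairs = []
    for rd, ei, mi in cands:
        if rd > rel_tolerance:
            break
        if ei in used_e or mi in used_m:
            continue
        used_e.add(ei)
        used_m.add(mi)
        pairs.append(
            {
                "experimental_d": float(exp_d[ei]),
                "model_d": float(model_d[mi]),
                "rel_diff": float(rd),
            }
        )
    pairs.sort(key=lambda p: -p["experimental_d"])
    return PeakMatchReport(
        pairs=pairs,
        matched=len(pairs),
        n_experimental=len(exp_d),
        tolerance=rel_tolerance,
    )
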