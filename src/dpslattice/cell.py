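"""Triclinic unit-cell mathematics.

Everything downstream (center generation, structure factors, powder
simulation, lattice inference) is phrased in terms of a P1 triclinic cell:
edge lengths ``a, b, c`` in Angstrom and inter-axial angles ``alpha, beta,
gamma`` in degrees.  The module provides the direct metric tensor, cell
volume, interplanar distances, Friedel-canonical reflection enumeration and
conversions among d-spacing, momentum transfer q and scattering angle 2theta.

Unit conventions
----------------
Lengths are Angstrom throughout the package (several source dimensions are
printed with nm units where Angstrom is clearly meant; all such values are
interpreted as Angstrom).  Angles cross the API in degrees; trigonometry is
done in radians internally.  The momentum-transfer convention is
``q = 4 pi sin(theta) / lambda`` with ``d = 2 pi / q``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "UnitCell",
    "Reflection",
    "ScatteringGeometry",
    "metric_tensor",
    "cell_volume",
    "d_spacing",
    "enumerate_reflections",
    "bragg_convert",
    "canonical_hkl",
    "cell_from_basis",
    "canonicalize_basis",
]


@dataclass(frozen=True)
class UnitCell:
    """Triclinic (P1) unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if not getattr(self, name) > 0:
                raise ValueError(f"cell length {name} must be > 0, got {getattr(self, name)}")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie strictly in (0, 180) degrees, got {ang}")
        if self.discriminant <= 0:
            raise ValueError(
                "angle combination is not geometrically realizable: "
                "1 - cos^2(alpha) - cos^2(beta) - cos^2(gamma) "
                f"+ 2 cos(alpha) cos(beta) cos(gamma) = {self.discriminant:.3e} <= 0"
            )

    @property
    def discriminant(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def angles(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    def basis(self) -> np.ndarray:
        """Row-vector lattice basis (3x3, Angstrom).

        Standard crystallographic orientation: ``a`` along x, ``b`` in the
        xy-plane, ``c`` completing a right-handed set.  Cartesian points are
        ``fractional @ basis``.
        """
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        cx = self.c * cb
        cy = self.c * (ca - cb * cg) / sg
        cz2 = self.c * self.c - cx * cx - cy * cy
        cz = math.sqrt(max(cz2, 0.0))
        return np.array(
            [
                [self.a, 0.0, 0.0],
                [self.b * cg, self.b * sg, 0.0],
                [cx, cy, cz],
            ]
        )

    def metric_tensor(self) -> np.ndarray:
        return metric_tensor(self)

    def volume(self) -> float:
        return cell_volume(self)

    def d_spacing(self, hkl: Sequence[int]) -> float:
        return d_spacing(self, hkl)

    # -- flat config (de)serialization -------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnitCell":
        return cls(
            a=float(d["a"]),
            b=float(d["b"]),
            c=float(d["c"]),
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            gamma=float(d["gamma"]),
        )


#: The triclinic cell fitted to the in vitro DNA-Dps crystal
#: (a = b = 83.3 A, c = 54.2 A, alpha = beta = gamma = 60.5 deg).
DPS_CRYSTAL_CELL = UnitCell(83.3, 83.3, 54.2, 60.5, 60.5, 60.5)


@dataclass
class Reflection:
    """A Friedel-canonical Bragg reflection with its interplanar distance."""

    h: int
    k: int
    l: int
    d: float
    weight: float = 0.0

    def __post_init__(self) -> None:
        if (self.h, self.k, self.l) == (0, 0, 0):
            raise ValueError("(0,0,0) is not a reflection")
        if self.d <= 0:
            raise ValueError("interplanar distance must be > 0")
        if self.weight < 0:
            raise ValueError("reflection weight must be >= 0")

    @property
    def hkl(self) -> tuple[int, int, int]:
        return (self.h, self.k, self.l)


@dataclass
class ScatteringGeometry:
    """Flat-detector powder geometry.

    wavelength in Angstrom, sample-detector distance and pixel size in mm,
    beam center in (row, column) pixel coordinates.
    """

    wavelength: float = 1.542
    sample_detector_distance: float = 2000.0
    beam_center: tuple[float, float] = (255.5, 255.5)
    pixel_size: float = 0.3

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be > 0")
        if self.sample_detector_distance <= 0:
            raise ValueError("sample-detector distance must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")

    def two_theta_deg(self, radius_mm: np.ndarray | float) -> np.ndarray | float:
        """Scattering angle 2theta (degrees) at radial distance r on the detector."""
        return np.degrees(np.arctan2(radius_mm, self.sample_detector_distance))

    def radius_mm(self, two_theta_deg: np.ndarray | float) -> np.ndarray | float:
        return self.sample_detector_distance * np.tan(np.radians(two_theta_deg))

    def to_dict(self) -> dict:
        return {
            "wavelength_angstrom": self.wavelength,
            "sample_detector_distance_mm": self.sample_detector_distance,
            "beam_center_px": list(self.beam_center),
            "pixel_size_mm": self.pixel_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScatteringGeometry":
        return cls(
            wavelength=float(d["wavelength_angstrom"]),
            sample_detector_distance=float(d["sample_detector_distance_mm"]),
            beam_center=tuple(float(x) for x in d["beam_center_px"]),
            pixel_size=float(d["pixel_size_mm"]),
        )


def metric_tensor(cell: UnitCell) -> np.ndarray:
    """Direct metric tensor G[i][j] = v_i . v_j (Angstrom^2)."""
    B = cell.basis()
    return B @ B.T


def cell_volume(cell: UnitCell) -> float:
    """Cell volume abc * sqrt(1 - cos^2 a - cos^2 b - cos^2 g + 2 cos a cos b cos g)."""
    return cell.a * cell.b * cell.c * math.sqrt(cell.discriminant)


def d_spacing(cell: UnitCell, hkl: Sequence[int]) -> float:
    """Interplanar distance d(hkl) = 1 / |h a* + k b* + l c*| in Angstrom."""
    h = np.asarray(hkl, dtype=float)
    if h.shape != (3,):
        raise ValueError("hkl must be a triple")
    if np.all(h == 0):
        raise ValueError("(0,0,0) has no interplanar distance")
    G_inv = np.linalg.inv(metric_tensor(cell))
    return 1.0 / math.sqrt(float(h @ G_inv @ h))


def canonical_hkl(hkl: Sequence[int]) -> tuple[int, int, int]:
    """Friedel-canonical representative: first nonzero index positive."""
    h, k, l = (int(x) for x in hkl)
    if (h, k, l) == (0, 0, 0):
        raise ValueError("(0,0,0) has no canonical form")
    for x in (h, k, l):
        if x != 0:
            if x < 0:
                return (-h, -k, -l)
            return (h, k, l)
    raise AssertionError("unreachable")


def enumerate_reflections(cell: UnitCell, d_min: float) -> list[Reflection]:
    """All Friedel-canonical reflections with d >= d_min, sorted by descending d.

    The index search box is bounded per axis by ``ceil(|v_i| / d_min) + 1``
    with ``v_i`` the direct lattice vectors: since ``1/d = |h a* + k b* + l c*|``
    and ``h = v_h . (h a* + k b* + l c*)``, Cauchy-Schwarz gives
    ``|h| <= |v_h| / d``, so the bound covers every admissible index.
    """
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    B = cell.basis()
    G_inv = np.linalg.inv(B @ B.T)
    bounds = [int(math.ceil(np.linalg.norm(B[i]) / d_min)) + 1 for i in range(3)]
    out: list[Reflection] = []
    for h, k, l in itertools.product(*(range(-n, n + 1) for n in bounds)):
        if (h, k, l) == (0, 0, 0):
            continue
        if canonical_hkl((h, k, l)) != (h, k, l):
            continue
        v = np.array([h, k, l], dtype=float)
        inv_d2 = float(v @ G_inv @ v)
        d = 1.0 / math.sqrt(inv_d2)
        if d >= d_min:
            out.append(Reflection(h, k, l, d))
    out.sort(key=lambda r: (-r.d, r.hkl))
    return out


_UNITS = {"d_angstrom", "q_inv_angstrom", "two_theta_deg"}


def bragg_convert(
    value: float,
    from_unit: str,
    to_unit: str,
    wavelength: float | None = None,
) -> float:
    """Convert among d (A), q (1/A) and 2theta (degrees).

    q = 4 pi sin(theta) / lambda, d = 2 pi / q, 2theta = 2 arcsin(lambda / 2d).
    The wavelength is required whenever ``two_theta_deg`` is involved.
    """
    for u in (from_unit, to_unit):
        if u not in _UNITS:
            raise ValueError(f"unknown unit {u!r}; expected one of {sorted(_UNITS)}")
    if value <= 0:
        raise ValueError("value must be strictly positive")
    needs_lambda = "two_theta_deg" in (from_unit, to_unit)
    if needs_lambda:
        if wavelength is None or wavelength <= 0:
            raise ValueError("a positive wavelength is required for 2theta conversions")

    # normalize to d
    if from_unit == "d_angstrom":
        d = value
    elif from_unit == "q_inv_angstrom":
        d = 2.0 * math.pi / value
    else:  # two_theta_deg
        if not 0.0 < value < 180.0:
            raise ValueError("2theta must lie in (0, 180) degrees")
        d = wavelength / (2.0 * math.sin(math.radians(value / 2.0)))

    if to_unit == "d_angstrom":
        return d
    if to_unit == "q_inv_angstrom":
        return 2.0 * math.pi / d
    # to two_theta_deg
    s = wavelength / (2.0 * d)
    if s >= 1.0:
        raise ValueError(
            f"reflection unreachable: lambda = {wavelength} A >= 2 d = {2 * d} A"
        )
    return 2.0 * math.degrees(math.asin(s))


# ---------------------------------------------------------------------------
# basis <-> cell and presentation reduction
# ---------------------------------------------------------------------------

def cell_from_basis(basis: np.ndarray) -> UnitCell:
    """Cell constants of a 3x3 row-vector basis."""
    B = np.asarray(basis, dtype=float)
    if B.shape != (3, 3):
        raise ValueError("basis must be 3x3")
    a, b, c = (float(np.linalg.norm(B[i])) for i in range(3))

    def ang(i: int, j: int) -> float:
        cosv = float(B[i] @ B[j]) / (np.linalg.norm(B[i]) * np.linalg.norm(B[j]))
        return math.degrees(math.acos(min(1.0, max(-1.0, cosv))))

    return UnitCell(a, b, c, ang(1, 2), ang(0, 2), ang(0, 1))


def _pair_reduce(B: np.ndarray) -> np.ndarray:
    """Lagrange-style pair reduction toward a short (near-Niggli) basis."""
    B = B.copy()
    changed = True
    it = 0
    while changed and it < 100:
        changed = False
        it += 1
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                m = round(float(B[i] @ B[j]) / float(B[j] @ B[j]))
                if m != 0:
                    cand = B[i] - m * B[j]
                    if cand @ cand < B[i] @ B[i] - 1e-12 * (B[i] @ B[i]):
                        B[i] = cand
                        changed = True
    return B


def canonicalize_basis(basis: np.ndarray, length_factor: float = 1.3) -> np.ndarray:
    """Deterministic presentation basis for a lattice.

    First reduce to a short basis, then search small unimodular
    re-combinations (coefficients in [-2, 2], vector length capped at
    ``length_factor`` times the longest reduced vector) and pick the triple
    whose inter-axial angles are all acute-or-right with the *most isometric*
    angle set: fewest obtuse angles first, then minimal spread (std) of the
    three angles, then minimal total squared length.  Vectors are ordered
    longest-first (the rhombohedral-like Dps crystal cell is conventionally
    reported a = b > c) and the result is right-handed.

    For lattices whose neighbor shells merge into near-equal distance
    families (the Dps trimer crystal) this selects the equal-angle setting a
    crystallographer would report rather than the raw shortest basis.
    """
    B0 = _pair_reduce(np.asarray(basis, dtype=float))
    if abs(np.linalg.det(B0)) < 1e-9:
        raise ValueError("basis is singular")
    max_len = max(np.linalg.norm(B0[i]) for i in range(3)) * length_factor

    coeffs = [
        np.array(t)
        for t in itertools.product(range(-2, 3), repeat=3)
        if t != (0, 0, 0)
    ]
    # antipodal dedup: keep canonical sign only
    coeffs = [t for t in coeffs if canonical_hkl(t) == tuple(t)]
    cands = []
    for t in coeffs:
        v = t @ B0
        n = float(np.linalg.norm(v))
        if n <= max_len:
            cands.append((t, v, n))
    cands.sort(key=lambda x: x[2])

    best_key = None
    best_B = None
    for (ti, vi, ni), (tj, vj, nj), (tk, vk, nk) in itertools.combinations(cands, 3):
        M = np.array([ti, tj, tk])
        if abs(round(float(np.linalg.det(M)))) != 1:
            continue
        # choose signs of the 2nd and 3rd vectors for the best angle set
        for sj, sk in itertools.product((1, -1), repeat=2):
            V = np.array([vi, sj * vj, sk * vk])
            cos01 = float(V[0] @ V[1]) / (ni * nj)
            cos02 = float(V[0] @ V[2]) / (ni * nk)
            cos12 = float(V[1] @ V[2]) / (nj * nk)
            angs = np.degrees(np.arccos(np.clip([cos12, cos02, cos01], -1, 1)))
            n_obtuse = int(np.sum(angs > 90.0 + 1e-9))
            key = (
                n_obtuse,
                round(float(np.std(angs)), 6),
                round(ni * ni + nj * nj + nk * nk, 6),
            )
            if best_key is None or key < best_key:
                best_key = key
                best_B = V
    if best_B is None:  # pragma: no cover - the reduced basis itself qualifies
        best_B = B0

    # longest-first ordering; stable tie-break on coordinates
    order = sorted(range(3), key=lambda i: (-np.linalg.norm(best_B[i]), tuple(best_B[i])))
    best_B = best_B[order]
    if np.linalg.det(best_B) < 0:
        best_B = -best_B
    return best_B


def canonical_cell(cell: UnitCell) -> UnitCell:
    """The presentation-convention cell of the lattice spanned by ``cell``."""
    return cell_from_basis(canonicalize_basis(cell.basis()))
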