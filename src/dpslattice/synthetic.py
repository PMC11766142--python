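"""Synthetic inputs with known ground truth.

Generators for every object the pipeline consumes: finite jittered P1
lattices of trimer centers, point-scatterer crystals with a DNA rod threaded
through the inter-trimer channel, 1D powder curves (smooth background +
Gaussian Bragg peaks + counting noise), azimuthally symmetric detector
images, and 2D projection images of center sets.

All generators are deterministic for a fixed seed (``numpy.random.default_rng``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .cell import ScatteringGeometry, UnitCell, DPS_CRYSTAL_CELL

__all__ = [
    "CenterSet",
    "ScattererSet",
    "Curve1D",
    "DetectorImage",
    "generate_lattice_centers",
    "generate_crystal_scatterers",
    "trimer_motif",
    "synthesize_powder_curve",
    "render_detector_image",
    "generate_projection_image",
    "demo_trimer_centers",
]


@dataclass
class CenterSet:
    """A 3D point cloud of oligomer centers (Angstrom)."""

    points: np.ndarray
    label: str = ""
    ground_truth: Optional[dict] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if len(self.points) < 1:
            raise ValueError("a CenterSet needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("all coordinates must be finite")
        if self.ground_truth is not None and "extents" in self.ground_truth:
            n_max = int(np.prod(self.ground_truth["extents"]))
            if len(self.points) > n_max:
                raise ValueError("more points than lattice nodes in ground truth")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ScattererSet:
    """Point/Gaussian scatterers: positions (A), weights, Gaussian widths (A)."""

    sites: np.ndarray
    weights: np.ndarray
    widths: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.sites = np.asarray(self.sites, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.sites.ndim != 2 or self.sites.shape[1] != 3 or len(self.sites) < 1:
            raise ValueError("sites must be a non-empty (N, 3) array")
        if self.weights.shape != (len(self.sites),) or self.widths.shape != (len(self.sites),):
            raise ValueError("weights and widths must match the number of sites")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


@dataclass
class Curve1D:
    """1D scattering curve: abscissa (2theta deg or q 1/A), intensities >= 0."""

    x: np.ndarray
    y: np.ndarray
    x_kind: str = "two_theta_deg"
    wavelength: float = 1.542
    valid: Optional[np.ndarray] = None
    counts: Optional[np.ndarray] = None  # contributing pixels per bin, if binned

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x_kind not in ("two_theta_deg", "q_inv_angstrom"):
            raise ValueError(f"unknown abscissa kind {self.x_kind!r}")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1D arrays of equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("abscissa must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(len(self.x), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.x.shape:
                raise ValueError("valid mask must match the grid")
        if np.any(self.y[self.valid] < 0):
            raise ValueError("intensities must be >= 0")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class DetectorImage:
    """2D intensity raster plus beam geometry; optional dead-pixel mask."""

    data: np.ndarray
    geometry: ScatteringGeometry
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("detector data must be 2D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("detector intensities must be finite")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask must match the raster shape")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_lattice_centers(
    cell: UnitCell,
    extents: Sequence[int],
    jitter_sigma: float = 0.0,
    vacancy_rate: float = 0.0,
    seed: int | np.random.Generator | None = 0,
) -> CenterSet:
    """Finite P1 lattice of centers with Gaussian jitter and vacancies.

    Nodes ``i a + j b + k c`` over the extent box, each retained with
    probability ``1 - vacancy_rate`` and displaced by isotropic Gaussian
    noise of per-axis standard deviation ``jitter_sigma`` (Angstrom).
    """
    extents = tuple(int(e) for e in extents)
    if len(extents) != 3 or any(e < 1 for e in extents):
        raise ValueError("extents must be three integers >= 1")
    if not 0.0 <= vacancy_rate < 1.0:
        raise ValueError("vacancy_rate must lie in [0, 1)")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    B = cell.basis()
    idx = np.stack(
        np.meshgrid(*(np.arange(e) for e in extents), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    pts = idx @ B
    keep = rng.random(len(pts)) >= vacancy_rate
    pts = pts[keep]
    if len(pts) == 0:
        raise ValueError(
            "all lattice nodes removed by vacancies; re-seed or lower vacancy_rate"
        )
    if jitter_sigma > 0:
        pts = pts + rng.normal(scale=jitter_sigma, size=pts.shape)
    gt = {
        "cell": cell,
        "jitter_sigma": float(jitter_sigma),
        "vacancy_rate": float(vacancy_rate),
        "extents": extents,
    }
    return CenterSet(points=pts, label="synthetic lattice", ground_truth=gt)


def demo_trimer_centers(seed: int = 0, n_centers: int = 150) -> CenterSet:
    """150 jittered trimer centers from the fitted Dps crystal cell.

    A (6, 6, 5) extent box (180 nodes) with 1.5 A jitter and 5% vacancies,
    subsampled to ``n_centers`` to emulate partial tomographic coverage.
    """
    rng = np.random.default_rng(seed)
    cs = generate_lattice_centers(
        DPS_CRYSTAL_CELL, (6, 6, 5), jitter_sigma=1.5, vacancy_rate=0.05, seed=rng
    )
    if len(cs) > n_centers:
        sel = rng.choice(len(cs), size=n_centers, replace=False)
        sel.sort()
        cs = CenterSet(cs.points[sel], label=cs.label, ground_truth=cs.ground_truth)
    return cs


def trimer_motif(radius: float = 20.0, weight: float = 18.7, width: float = 5.0) -> ScattererSet:
    """Three beads at 120 degrees on a circle: a torus-like trimer analogue.

    Stands in for the ~70 A diameter, ~44 A high toroidal Dps trimer; the
    bead circle radius defaults to 20 A so the beads sit mid-annulus.
    Scattering weights are in kDa-equivalent units (scattering power scales
    with molecular mass): one Dps monomer is ~18.7 kDa per bead.
    """
    ang = np.radians([90.0, 210.0, 330.0])
    sites = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(3)], axis=1)
    return ScattererSet(
        sites=sites,
        weights=np.full(3, weight),
        widths=np.full(3, width),
        label="trimer motif",
    )


def generate_crystal_scatterers(
    cell: UnitCell,
    extents: Sequence[int],
    motif: Optional[ScattererSet] = None,
    dna_rod: bool = False,
    rod_spacing: float = 3.4,
    rod_weight: float = 0.66,
    rod_width: float = 4.0,
    rod_offset_frac: tuple[float, float] = (0.5, 0.5),
    seed: int | None = 0,
) -> ScattererSet:
    """Point-scatterer crystal: the trimer motif on every node, optional DNA rods.

    Rods run parallel to the c axis through each (i, j) channel of the
    crystal at fractional in-plane offset ``rod_offset_frac``, with beads
    every ``rod_spacing`` Angstrom (default: the 3.4 A base-pair rise, at
    0.66 kDa per base pair so rod and trimer scattering powers sit in their
    physical mass ratio).
    """
    extents = tuple(int(e) for e in extents)
    if len(extents) != 3 or any(e < 1 for e in extents):
        raise ValueError("extents must be three integers >= 1")
    if motif is None:
        motif = trimer_motif()
    if len(motif) < 1:
        raise ValueError("trimer motif must be non-empty")
    if dna_rod and rod_spacing <= 0:
        raise ValueError("rod_spacing must be > 0 when the DNA rod is enabled")

    B = cell.basis()
    idx = np.stack(
        np.meshgrid(*(np.arange(e) for e in extents), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    nodes = idx @ B

    sites = (nodes[:, None, :] + motif.sites[None, :, :]).reshape(-1, 3)
    weights = np.tile(motif.weights, len(nodes))
    widths = np.tile(motif.widths, len(nodes))

    if dna_rod:
        c_len = float(np.linalg.norm(B[2]))
        c_hat = B[2] / c_len
        n_beads = int(math.floor(extents[2] * c_len / rod_spacing))
        ij = np.stack(
            np.meshgrid(np.arange(extents[0]), np.arange(extents[1]), indexing="ij"),
            axis=-1,
        ).reshape(-1, 2)
        offsets = (
            (ij[:, 0] + rod_offset_frac[0])[:, None] * B[0]
            + (ij[:, 1] + rod_offset_frac[1])[:, None] * B[1]
        )
        t = np.arange(n_beads) * rod_spacing
        rod_sites = (offsets[:, None, :] + t[None, :, None] * c_hat).reshape(-1, 3)
        sites = np.vstack([sites, rod_sites])
        weights = np.concatenate([weights, np.full(len(rod_sites), rod_weight)])
        widths = np.concatenate([widths, np.full(len(rod_sites), rod_width)])

    return ScattererSet(sites=sites, weights=weights, widths=widths, label="crystal")


def synthesize_powder_curve(
    peaks: Sequence[tuple[float, float, float]],
    background: tuple[float, float, float] = (0.0, 0.0, 0.0),
    grid: np.ndarray | None = None,
    noise: bool = False,
    seed: int | None = 0,
    wavelength: float = 1.542,
    x_kind: str = "two_theta_deg",
) -> Curve1D:
    """Smooth decaying background + Gaussian Bragg peaks + optional Poisson noise.

    peaks: iterable of (position, area, sigma) in grid units.
    background: (amplitude, decay_power, constant); evaluated as
    ``amplitude * (x / x[0]) ** (-decay_power) + constant``, emulating the
    smooth scattering of amorphous cell material under the Bragg peaks.
    """
    if grid is None:
        grid = np.linspace(0.2, 3.0, 1400)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    amp, power, const = background
    if amp != 0.0 and grid[0] <= 0:
        raise ValueError("power-law background requires a strictly positive grid")
    y = np.full_like(grid, float(const))
    if amp != 0.0:
        y = y + amp * (grid / grid[0]) ** (-power)
    for pos, area, sig in peaks:
        if sig <= 0:
            raise ValueError("peak sigma must be > 0")
        y = y + area / (sig * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((grid - pos) / sig) ** 2
        )
    if np.any(y < 0):
        raise ValueError("expected intensity is negative; check the background")
    if noise:
        rng = np.random.default_rng(seed)
        y = rng.poisson(y).astype(float)
    return Curve1D(x=grid, y=y, x_kind=x_kind, wavelength=wavelength)


def render_detector_image(
    curve: Curve1D,
    geometry: ScatteringGeometry,
    image_size: int = 512,
    noise: bool = False,
    seed: int | None = 0,
) -> DetectorImage:
    """Azimuthally symmetric detector image of a 1D curve.

    Each pixel takes the curve value at its 2theta (from radial distance,
    sample-detector distance and wavelength); pixels outside the curve's
    angular range are zero.  Optional Poisson counting noise.
    """
    if curve.x_kind != "two_theta_deg":
        raise ValueError("render expects a 2theta-gridded curve")
    n = int(image_size)
    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    r_mm = np.hypot(
        (rows - geometry.beam_center[0]) * geometry.pixel_size,
        (cols - geometry.beam_center[1]) * geometry.pixel_size,
    )
    tth = geometry.two_theta_deg(r_mm)
    in_range = (tth >= curve.x[0]) & (tth <= curve.x[-1])
    if not np.any(in_range):
        raise ValueError("no detector pixel falls inside the curve's angular range")
    img = np.zeros((n, n))
    img[in_range] = np.interp(tth[in_range], curve.x, curve.y)
    if noise:
        rng = np.random.default_rng(seed)
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    return DetectorImage(data=img, geometry=geometry)


_AXES = {"x": 0, "y": 1, "z": 2}


def generate_projection_image(
    centers: CenterSet,
    view_axis: str = "z",
    pixel_size: float = 2.0,
    psf_sigma: float = 4.0,
    pad_sigmas: float = 4.0,
) -> tuple[np.ndarray, float]:
    """Project centers along an axis and splat them as Gaussians.

    Returns (image, pixel_size).  A synthetic stand-in for a TEM projection
    of a crystal: no contrast transfer function, just a Gaussian PSF.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if len(centers) < 2:
        raise ValueError("need at least two centers to project")
    ax = _AXES.get(view_axis)
    if ax is None:
        raise ValueError("view_axis must be one of x, y, z")
    keep = [i for i in range(3) if i != ax]
    uv = centers.points[:, keep]
    lo = uv.min(axis=0) - pad_sigmas * psf_sigma
    hi = uv.max(axis=0) + pad_sigmas * psf_sigma
    shape = np.maximum(np.ceil((hi - lo) / pixel_size).astype(int) + 1, 16)
    img = np.zeros(shape)
    ij = np.round((uv - lo) / pixel_size).astype(int)
    np.add.at(img, (ij[:, 0], ij[:, 1]), 1.0)
    img = ndimage.gaussian_filter(img, sigma=psf_sigma / pixel_size)
    return img, float(pixel_size)
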