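"""Structure factors, Scherrer broadening, pattern synthesis and peak
matching against brute-force and analytic oracles."""

import math

import numpy as np
import pytest

from dpslattice import (
    UnitCell,
    enumerate_reflections,
    generate_crystal_scatterers,
    match_peaks,
    simulate_powder_pattern,
    size_broadening,
    structure_factor,
)
from dpslattice.reduction import estimate_background, pick_peaks
from dpslattice.synthetic import ScattererSet

from conftest import EXP_D, random_valid_cell

_SQ8LN2 = 2.0 * math.sqrt(2.0 * math.log(2.0))


def point_set(sites, weights=None, widths=None) -> ScattererSet:
    sites = np.atleast_2d(np.asarray(sites, float))
    n = len(sites)
    return ScattererSet(
        sites,
        np.ones(n) if weights is None else np.asarray(weights, float),
        np.zeros(n) if widths is None else np.asarray(widths, float),
    )


def brute_force_sf(scatterers: ScattererSet, cell: UnitCell, hkl) -> float:
    """Direct complex-exponential summation in extended precision."""
    frac = scatterers.sites @ np.linalg.inv(cell.basis())
    q = np.longdouble(2 * np.pi) / np.longdouble(cell.d_spacing(hkl))
    re = np.longdouble(0)
    im = np.longdouble(0)
    for x, w, s in zip(frac, scatterers.weights, scatterers.widths):
        phase = np.longdouble(2 * np.pi) * (
            np.longdouble(hkl[0]) * np.longdouble(x[0])
            + np.longdouble(hkl[1]) * np.longdouble(x[1])
            + np.longdouble(hkl[2]) * np.longdouble(x[2])
        )
        damp = np.exp(-np.longdouble(0.5) * (q * np.longdouble(s)) ** 2)
        re += np.longdouble(w) * damp * np.cos(phase)
        im += np.longdouble(w) * damp * np.sin(phase)
    return float(re * re + im * im)


class TestStructureFactor:
    def test_single_origin_scatterer_is_unity_everywhere(self, dps_cell):
        sc = point_set([[0.0, 0, 0]])
        for hkl in [(1, 0, 0), (0, 0, 1), (2, 1, 3)]:
            assert structure_factor(sc, dps_cell, hkl) == pytest.approx(1.0, rel=1e-12)

    def test_half_cell_translation_extinction(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        sc = point_set([[0.0, 0, 0], [5.0, 0, 0]])  # fractional (0,0,0), (1/2,0,0)
        assert structure_factor(sc, cell, (2, 0, 0)) == pytest.approx(4.0, rel=1e-10)
        assert structure_factor(sc, cell, (1, 0, 0)) == pytest.approx(0.0, abs=1e-20)

    def test_friedel_symmetry(self, dps_cell):
        rng = np.random.default_rng(3)
        sc = point_set(rng.uniform(0, 50, (7, 3)), rng.uniform(0.5, 2, 7), rng.uniform(0, 4, 7))
        assert structure_factor(sc, dps_cell, (1, 2, -1)) == pytest.approx(
            structure_factor(sc, dps_cell, (-1, -2, 1)), rel=1e-12
        )

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(41)
        for _ in range(60):
            cell = random_valid_cell(rng, lo=8.0, hi=20.0)
            sc = point_set(
                rng.uniform(-20, 20, (20, 3)),
                rng.uniform(0, 3, 20),
                rng.uniform(0, 3, 20),
            )
            hkl = tuple(rng.integers(-3, 4, 3))
            if hkl == (0, 0, 0):
                continue
            got = structure_factor(sc, cell, hkl)
            oracle = brute_force_sf(sc, cell, hkl)
            assert got == pytest.approx(oracle, rel=1e-10, abs=1e-18)

    def test_far_scatterer_warns(self, dps_cell):
        sc = point_set([[2000.0, 0, 0]])
        with pytest.warns(UserWarning, match="10 cells"):
            structure_factor(sc, dps_cell, (1, 0, 0))


class TestSizeBroadening:
    def test_matches_direct_scherrer_evaluation(self):
        tth = 1.2694
        sigma = size_broadening(tth, wavelength=1.542, crystallite_size=2000.0)
        fwhm = math.degrees(0.9 * 1.542 / (2000.0 * math.cos(math.radians(tth / 2))))
        assert fwhm == pytest.approx(0.040, abs=5e-4)
        assert sigma == pytest.approx(fwhm / _SQ8LN2, rel=1e-12)

    def test_vanishes_for_infinite_crystallite(self):
        assert size_broadening(1.0, 1.542, 1e15) < 1e-12
        assert size_broadening(1.0, 1.542, 1e15) > 0

    def test_doubling_size_halves_sigma(self):
        s1 = size_broadening(2.0, 1.542, 1000.0)
        s2 = size_broadening(2.0, 1.542, 2000.0)
        assert s1 == pytest.approx(2 * s2, rel=1e-12)

    def test_divergence_near_ninety_degrees(self):
        with pytest.raises(ValueError):
            size_broadening(180.0 - 1e-12, 1.542, 2000.0)


class TestSimulatePattern:
    def test_single_reflection_gaussian_shape_and_area(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        sc = point_set([[0.0, 0, 0]])
        pat = simulate_powder_pattern(
            cell, sc, wavelength=1.542, crystallite_size=2000.0, d_min=9.0,
            grid=np.linspace(7.0, 11.0, 8000),
        )
        # cubic a=10, d_min=9: three degenerate reflections at d=10
        assert len(pat.reflections) == 3
        area = np.trapezoid(pat.curve.y, pat.curve.x)
        assert area == pytest.approx(sum(2 * r.weight for r in pat.reflections), rel=1e-3)
        top = pat.curve.x[np.argmax(pat.curve.y)]
        assert top == pytest.approx(pat.peak_two_theta[0], abs=1e-3)

    def test_integrated_intensity_conserved_under_grid_refinement(self, dps_cell):
        sc = generate_crystal_scatterers(dps_cell, (1, 1, 1), dna_rod=True)
        areas = []
        for n in (4000, 8000):
            pat = simulate_powder_pattern(
                dps_cell, sc, d_min=30.0, grid=np.linspace(0.8, 3.2, n)
            )
            areas.append(np.trapezoid(pat.curve.y, pat.curve.x))
        oracle = sum(2 * r.weight for r in pat.reflections)
        for a in areas:
            assert a == pytest.approx(oracle, rel=1e-3)

    def test_equal_phase_superposition(self, dps_cell):
        # same sites, split weights: |F_union| = |F_1| + |F_2|
        rng = np.random.default_rng(5)
        sites = rng.uniform(0, 40, (6, 3))
        w = rng.uniform(0.5, 2.0, 6)
        s1 = point_set(sites, 0.3 * w)
        s2 = point_set(sites, 0.7 * w)
        su = point_set(sites, w)
        for hkl in [(1, 0, 0), (1, 1, 1), (0, 2, 1)]:
            f1 = math.sqrt(structure_factor(s1, dps_cell, hkl))
            f2 = math.sqrt(structure_factor(s2, dps_cell, hkl))
            fu = math.sqrt(structure_factor(su, dps_cell, hkl))
            assert fu == pytest.approx(f1 + f2, rel=1e-9)

    def test_visible_model_peaks_cover_experimental_rings(self, dps_cell):
        """The trimer/DNA-rod model's visible powder peaks line up with the
        four measured interplanar distances at 5% tolerance."""
        sc = generate_crystal_scatterers(dps_cell, (1, 1, 1), dna_rod=True)
        pat = simulate_powder_pattern(dps_cell, sc, 1.542, 2000.0, d_min=30.0)
        baseline = estimate_background(pat.curve, window=25)
        peaks = pick_peaks(pat.curve, baseline, min_prominence=0.02)
        report = match_peaks(peaks.d_values, EXP_D, rel_tolerance=0.05)
        assert report.matched == len(EXP_D)

    def test_reextracted_positions_within_half_sigma(self, dps_cell):
        sc = generate_crystal_scatterers(dps_cell, (1, 1, 1), dna_rod=True)
        pat = simulate_powder_pattern(dps_cell, sc, d_min=30.0)
        baseline = estimate_background(pat.curve, window=25)
        peaks = pick_peaks(pat.curve, baseline, min_prominence=0.02)
        wmax = max(r.weight for r in pat.reflections)
        all_tth = pat.peak_two_theta
        strong = [r.weight > 0.05 * wmax for r in pat.reflections]
        checked = 0
        for i, (tth, is_strong) in enumerate(zip(all_tth, strong)):
            if not is_strong:
                continue
            sigma = size_broadening(tth, 1.542, 2000.0)
            # only isolated peaks: a non-degenerate neighbor within 3 sigma
            # blends the maximum (exact twins share the same maximum)
            gaps = np.abs(np.delete(all_tth, i) - tth)
            if np.any((gaps > 1e-9) & (gaps < 3 * sigma)):
                continue
            nearest = min(abs(e["two_theta_deg"] - tth) for e in peaks.entries)
            assert nearest < 0.5 * sigma
            checked += 1
        assert checked >= 3


class TestMatchPeaks:
    def test_identical_lists_fully_matched(self):
        rep = match_peaks([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        assert rep.matched == 3
        assert all(p["rel_diff"] == 0 for p in rep.pairs)

    def test_disjoint_lists_no_match(self):
        rep = match_peaks([10.0], [20.0], rel_tolerance=0.05)
        assert rep.matched == 0

    def test_each_value_used_once(self):
        rep = match_peaks([10.0], [10.0, 10.2], rel_tolerance=0.05)
        assert rep.matched == 1

    def test_enumerated_dps_reflections_match_all_four_rings(self, dps_cell):
        model_d = [r.d for r in enumerate_reflections(dps_cell, d_min=30.0)]
        rep = match_peaks(model_d, EXP_D, rel_tolerance=0.05)
        assert rep.matched == 4
        assert rep.all_matched

    def test_empty_experimental_rejected(self):
        with pytest.raises(ValueError):
            match_peaks([10.0], [])
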