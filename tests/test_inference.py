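"""Lattice recovery from center clouds: distribution functions, the
cluster-and-refine cell fit, and FFT periodicity extraction, each against
exhaustive or analytic oracles on noiseless lattices."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from dpslattice import (
    UnitCell,
    canonical_cell,
    demo_trimer_centers,
    generate_lattice_centers,
    generate_projection_image,
    infer_lattice,
    pair_angle_distribution,
    pair_distance_distribution,
    spacing_from_projection,
)
from dpslattice.synthetic import CenterSet

from conftest import random_valid_cell

CONSTANTS = ("a", "b", "c", "alpha", "beta", "gamma")


def cells_close(c1: UnitCell, c2: UnitCell, rel_len=1e-6, abs_ang=1e-4) -> bool:
    return all(
        abs(getattr(c1, n) - getattr(c2, n)) <= rel_len * getattr(c2, n) for n in "abc"
    ) and all(
        abs(getattr(c1, n) - getattr(c2, n)) <= abs_ang
        for n in ("alpha", "beta", "gamma")
    )


class TestPairDistanceDistribution:
    def test_two_points_single_mode(self):
        cs = CenterSet(np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        modes = pair_distance_distribution(cs, r_max=80.0)
        assert len(modes.modes) == 1
        assert modes.modes[0]["location"] == pytest.approx(50.0, abs=0.5)

    def test_noiseless_dps_lattice_modes_match_exhaustive_distances(self, dps_cell):
        cs = generate_lattice_centers(dps_cell, (6, 6, 5))
        modes = pair_distance_distribution(cs, r_max=100.0)
        # oracle: distinct pairwise-distance families on the noiseless lattice
        fam = np.unique(np.round(pdist(cs.points), 1))
        fam = fam[fam <= 100.0]
        # |c| = 54.2, |a-c| = |b-c| = 73.7, merged {|a|,|b|,|a-b|} near 83-84
        locs = modes.locations
        for expected in (54.2, 73.7):
            assert np.min(np.abs(locs - expected)) < 0.5
            assert np.min(np.abs(fam - expected)) < 0.1
        assert np.min(np.abs(locs - 83.5)) < 0.7  # merged family mode

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            pair_distance_distribution(CenterSet(np.zeros((1, 3))))

    def test_no_pair_within_rmax_rejected(self):
        cs = CenterSet(np.array([[0.0, 0, 0], [500.0, 0, 0]]))
        with pytest.raises(ValueError):
            pair_distance_distribution(cs, r_max=100.0)

    def test_modes_independent_of_point_ordering(self):
        rng = np.random.default_rng(0)
        cs = demo_trimer_centers(seed=2)
        perm = rng.permutation(len(cs))
        shuffled = CenterSet(cs.points[perm])
        m1 = pair_distance_distribution(cs)
        m2 = pair_distance_distribution(shuffled)
        np.testing.assert_array_equal(m1.locations, m2.locations)


class TestPairAngleDistribution:
    def test_equilateral_triangle_mode_at_60(self):
        cs = CenterSet(
            np.array([[0.0, 0, 0], [10.0, 0, 0], [5.0, 5 * np.sqrt(3), 0]])
        )
        modes = pair_angle_distribution(cs, neighbor_cutoff=15.0)
        assert modes.modes[0]["location"] == pytest.approx(60.0, abs=1.0)

    def test_collinear_points_single_mode_at_180(self):
        cs = CenterSet(np.array([[float(i) * 10, 0, 0] for i in range(5)]))
        modes = pair_angle_distribution(cs, neighbor_cutoff=15.0)
        assert len(modes.modes) == 1
        assert modes.modes[0]["location"] == pytest.approx(180.0, abs=1.5)

    def test_noiseless_dps_lattice_has_acute_and_obtuse_modes(self, dps_cell):
        cs = generate_lattice_centers(dps_cell, (6, 6, 5))
        modes = pair_angle_distribution(cs, neighbor_cutoff=90.0)
        locs = modes.locations
        assert np.min(np.abs(locs - 60.5)) < 1.5
        assert np.min(np.abs(locs - 120.0)) < 2.5

    def test_too_few_neighbors_rejected(self):
        cs = CenterSet(np.array([[0.0, 0, 0], [500.0, 0, 0], [0, 500.0, 0]]))
        with pytest.raises(ValueError):
            pair_angle_distribution(cs, neighbor_cutoff=10.0)


class TestInferLattice:
    def test_noiseless_cubic_exact_recovery(self):
        cell = UnitCell(10, 10, 10, 90, 90, 90)
        cs = generate_lattice_centers(cell, (3, 3, 3))
        fit = infer_lattice(cs, neighbor_cutoff=15.0, cluster_tolerance=1.0)
        assert cells_close(fit.cell, cell)
        assert fit.residual < 1e-9

    def test_noiseless_dps_cell_exact_recovery(self, dps_cell):
        cs = generate_lattice_centers(dps_cell, (6, 6, 5))
        fit = infer_lattice(cs)
        assert cells_close(fit.cell, dps_cell)

    def test_exact_recovery_on_random_cells(self):
        rng = np.random.default_rng(31)
        n_done = 0
        while n_done < 10:
            cell = random_valid_cell(rng, lo=8.0, hi=14.0)
            cs = generate_lattice_centers(cell, (3, 3, 3))
            fit = infer_lattice(
                cs, neighbor_cutoff=1.6 * max(cell.lengths), cluster_tolerance=0.5
            )
            assert cells_close(fit.cell, canonical_cell(cell))
            n_done += 1

    def test_rigid_motion_invariance(self, dps_cell):
        cs = demo_trimer_centers(seed=4)
        rng = np.random.default_rng(7)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        moved = CenterSet(cs.points @ Q.T + np.array([123.0, -45.0, 67.0]))
        f1 = infer_lattice(cs)
        f2 = infer_lattice(moved)
        for name in CONSTANTS:
            assert getattr(f2.cell, name) == pytest.approx(
                getattr(f1.cell, name), rel=1e-9, abs=1e-9
            )

    def test_jittered_recovery_within_two_percent(self, dps_cell):
        fit = infer_lattice(demo_trimer_centers(seed=0))
        lengths = sorted(fit.cell.lengths)
        assert lengths[2] == pytest.approx(83.3, rel=0.02)
        assert lengths[1] == pytest.approx(83.3, rel=0.02)
        assert lengths[0] == pytest.approx(54.2, rel=0.02)
        assert np.mean(fit.cell.angles) == pytest.approx(60.5, abs=2.0)
        assert all(v >= 0 for v in fit.uncertainties.values())

    def test_monotone_degradation_with_jitter(self, dps_cell):
        errs = []
        for sigma in (0.0, 0.75, 1.5):
            rel = []
            for seed in range(5):
                cs = generate_lattice_centers(dps_cell, (6, 6, 5), sigma, 0.05, seed)
                fit = infer_lattice(cs)
                lengths = sorted(fit.cell.lengths)
                rel.append(
                    abs(lengths[2] - 83.3) / 83.3 + abs(lengths[0] - 54.2) / 54.2
                )
            errs.append(np.mean(rel))
        assert errs[0] < 1e-9
        assert errs[0] <= errs[1] <= errs[2]
        assert errs[2] < 0.04  # < 2% per constant at sigma = 1.5 A

    def test_coplanar_points_rejected(self):
        pts = np.array(
            [[i * 10.0, j * 10.0, 0.0] for i in range(3) for j in range(3)]
        )
        with pytest.raises(ValueError):
            infer_lattice(CenterSet(pts), neighbor_cutoff=15.0, cluster_tolerance=1.0)

    def test_too_few_centers_rejected(self):
        with pytest.raises(ValueError):
            infer_lattice(CenterSet(np.random.default_rng(0).normal(size=(5, 3))))


class TestSpacingFromProjection:
    def test_sinusoidal_stripes_period_ten_pixels(self):
        x = np.arange(128)
        img = 1.0 + np.cos(2 * np.pi * x / 10.0)[None, :] * np.ones((128, 1))
        out = spacing_from_projection(img, pixel_size=1.0)
        assert out
        assert out[0]["spacing_angstrom"] == pytest.approx(10.0, rel=0.05)

    def test_uniform_image_gives_empty_result(self):
        assert spacing_from_projection(np.ones((64, 64)), pixel_size=1.0) == []

    def test_lattice_projection_matches_analytic_row_spacing(self, dps_cell):
        # rotate the lattice so c is along z, project along z; the projected
        # 2D lattice is spanned by the projections of a and b
        B = dps_cell.basis()
        c_hat = B[2] / np.linalg.norm(B[2])
        # rotation sending c_hat -> z
        z = np.array([0.0, 0.0, 1.0])
        v = np.cross(c_hat, z)
        s, c = np.linalg.norm(v), float(c_hat @ z)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
        cs = generate_lattice_centers(dps_cell, (8, 8, 2))
        rotated = CenterSet(cs.points @ R.T)
        img, px = generate_projection_image(rotated, "z", pixel_size=3.0, psf_sigma=6.0)
        out = spacing_from_projection(img, pixel_size=px)
        assert out
        # analytic row spacings of the projected (a', b') lattice
        a2, b2 = (R @ B[0])[:2], (R @ B[1])[:2]
        area = abs(a2[0] * b2[1] - a2[1] * b2[0])
        rows = [
            area / np.linalg.norm(b2),
            area / np.linalg.norm(a2),
            area / np.linalg.norm(a2 - b2),
            area / np.linalg.norm(a2 + b2),
        ]
        got = out[0]["spacing_angstrom"]
        assert min(abs(got - r) / r for r in rows) < 0.05
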