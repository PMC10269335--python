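"""Superposition, RMSD/RMSF, hydrogen bonds and torsions."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conftest import random_rigid_transform
from pnadyn import fixtures as fx
from pnadyn.traj_metrics import (
    AtomSelection,
    HBondCriterion,
    TrajectoryEnsemble,
    apply_transform,
    dihedral,
    dihedral_series,
    hbond_occupancy,
    rmsd_series,
    rmsf,
    superpose,
    torsion_histogram,
)


def rotation_search_rmsd(mobile, reference):
    """Independent oracle: RMSD minimized by explicit rotation search.

    Centers both point sets, scans a coarse Euler-angle grid, then polishes
    the best grid point with a derivative-free local optimizer.  Never touches
    the SVD/Kabsch route.
    """
    m = mobile - mobile.mean(axis=0)
    r = reference - reference.mean(axis=0)

    def cost(euler):
        R = Rotation.from_euler("zyz", euler, degrees=True).as_matrix()
        d = m @ R.T - r
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))

    grid = np.arange(0.0, 360.0, 30.0)
    half = np.arange(0.0, 181.0, 30.0)
    best, best_cost = None, np.inf
    for a in grid:
        for b in half:
            for c in grid:
                v = cost((a, b, c))
                if v < best_cost:
                    best, best_cost = (a, b, c), v
    res = minimize(cost, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000})
    return float(res.fun)


class TestSuperpose:
    def test_self_superposition_zero(self, rng):
        frame = rng.uniform(-5, 5, (10, 3))
        assert superpose(frame, frame).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_recovers_zero_rmsd(self, rng):
        frame = rng.uniform(-5, 5, (10, 3))
        R, t = random_rigid_transform(rng)
        moved = frame @ R.T + t
        result = superpose(moved, frame)
        assert result.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(apply_transform(moved, result), frame, atol=1e-9)

    def test_matches_rotation_search_oracle_on_four_atom_toys(self, rng):
        for _ in range(2):
            mobile = rng.uniform(-3, 3, (4, 3))
            reference = rng.uniform(-3, 3, (4, 3))
            assert superpose(mobile, reference).rmsd == pytest.approx(
                rotation_search_rmsd(mobile, reference), abs=1e-6)

    def test_matches_mdanalysis(self, rng):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd
        mobile = rng.uniform(-4, 4, (12, 3))
        reference = mobile + rng.normal(0, 0.5, (12, 3))
        assert superpose(mobile, reference).rmsd == pytest.approx(
            mda_rmsd(mobile, reference, center=True, superposition=True), abs=1e-8)

    def test_degenerate_selection_errors(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)
        two = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError, match="at least 3"):
            superpose(two, two)


class TestRmsdSeries:
    def make_traj(self, coords):
        atoms = fx.build_duplex(fx.DuplexRecipe(noise_sd=0.0)).atoms[: coords.shape[1]]
        return TrajectoryEnsemble(coords=coords, atoms=atoms)

    def test_constant_trajectory_all_zero(self, rng):
        frame = rng.uniform(-5, 5, (8, 3))
        traj = self.make_traj(np.repeat(frame[None], 5, axis=0))
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-12)

    def test_rigid_body_motion_is_invisible(self, rng):
        frame = rng.uniform(-5, 5, (8, 3))
        frames = []
        for _ in range(5):
            R, t = random_rigid_transform(rng)
            frames.append(frame @ R.T + t)
        traj = self.make_traj(np.stack(frames))
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-9)

    def test_zero_at_reference_and_nonnegative(self, rng):
        coords = rng.uniform(-5, 5, (6, 8, 3))
        traj = self.make_traj(coords)
        series = rmsd_series(traj, reference_frame_index=2)
        assert series[2] == pytest.approx(0.0, abs=1e-12)
        assert np.all(series >= 0)

    def test_single_displaced_atom_against_direct_computation(self, rng):
        """One atom displaced by d in one frame, checked against an explicit
        superpose-then-measure computation (the optimal fit redistributes a
        small part of the displacement)."""
        frame = rng.uniform(-5, 5, (20, 3))
        moved = frame.copy()
        d = 0.8
        moved[7, 0] += d
        traj = self.make_traj(np.stack([frame, moved]))
        series = rmsd_series(traj, reference_frame_index=0)
        direct = superpose(moved, frame).rmsd
        assert series[1] == pytest.approx(direct, abs=1e-12)
        # the unfitted value has the closed form d / sqrt(N)
        raw = rmsd_series(traj, reference_frame_index=0, fit=False)
        assert raw[1] == pytest.approx(d / np.sqrt(20), abs=1e-12)
        assert series[1] <= raw[1] + 1e-12


class TestRmsf:
    def make_traj(self, coords):
        atoms = fx.build_duplex(fx.DuplexRecipe(noise_sd=0.0)).atoms[: coords.shape[1]]
        return TrajectoryEnsemble(coords=coords, atoms=atoms)

    def test_constant_trajectory_zero(self, rng):
        frame = rng.uniform(-5, 5, (10, 3))
        traj = self.make_traj(np.repeat(frame[None], 6, axis=0))
        np.testing.assert_allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_oscillating_atom_two_point_variance(self, rng):
        """An atom alternating +/- a about its mean has RMSF exactly a (no
        rigid-body motion, alignment disabled); with alignment on a large
        anchor set the fitted value approaches a with an O(a/N) correction."""
        frame = rng.uniform(-8, 8, (40, 3))
        a = 0.6
        up, down = frame.copy(), frame.copy()
        up[5, 2] += a
        down[5, 2] -= a
        traj = self.make_traj(np.stack([up, down, up, down]))
        exact = rmsf(traj, align=False)
        assert exact[5] == pytest.approx(a, abs=1e-12)
        np.testing.assert_allclose(np.delete(exact, 5), 0.0, atol=1e-12)
        fitted = rmsf(traj, align=True)
        assert fitted[5] == pytest.approx(a, rel=3.0 / 40)

    def test_invariant_under_global_rotation_of_all_frames(self, rng):
        coords = rng.uniform(-5, 5, (6, 10, 3))
        traj = self.make_traj(coords)
        R, t = random_rigid_transform(rng)
        rotated = self.make_traj(coords @ R.T + t)
        np.testing.assert_allclose(rmsf(traj), rmsf(rotated), atol=1e-8)

    def test_window_restricts_frames(self, rng):
        coords = np.repeat(rng.uniform(-5, 5, (1, 10, 3)), 6, axis=0)
        coords[5] += rng.normal(0, 1, (10, 3))  # noise only in the last frame
        traj = self.make_traj(coords)
        np.testing.assert_allclose(rmsf(traj, window=(0, 5)), 0.0, atol=1e-12)
        with pytest.raises(ValueError, match="empty"):
            rmsf(traj, window=(4, 4))


class TestHBondOccupancy:
    def linear_hbond_traj(self, d_a_distance, n_frames=5):
        """D-H...A collinear along x with the given donor-acceptor distance."""
        coords = np.zeros((n_frames, 4, 3))
        coords[:, 0] = [0.0, 0.0, 0.0]                 # D
        coords[:, 1] = [1.0, 0.0, 0.0]                 # H
        coords[:, 2] = [d_a_distance, 0.0, 0.0]        # A
        coords[:, 3] = [0.0, 5.0, 0.0]                 # spectator
        atoms = fx.build_duplex(fx.DuplexRecipe(noise_sd=0.0)).atoms[:4]
        return TrajectoryEnsemble(coords=coords, atoms=atoms)

    def test_linear_geometry_within_cutoff_full_occupancy(self):
        traj = self.linear_hbond_traj(2.9)
        occ = hbond_occupancy(traj, donors=[(0, 1)], acceptors=[2])
        assert occ[0, 0] == 1.0

    def test_beyond_distance_cutoff_zero(self):
        traj = self.linear_hbond_traj(3.6)
        occ = hbond_occupancy(traj, donors=[(0, 1)], acceptors=[2])
        assert occ[0, 0] == 0.0

    def test_angle_criterion_measured_at_hydrogen(self):
        # bent geometry: D-H-A angle 120 degrees but D-A still short
        coords = np.zeros((3, 3, 3))
        coords[:, 0] = [0.0, 0.0, 0.0]
        coords[:, 1] = [1.0, 0.0, 0.0]
        coords[:, 2] = [1.0 + 1.8 * np.cos(np.radians(60)),
                        1.8 * np.sin(np.radians(60)), 0.0]
        atoms = fx.build_duplex(fx.DuplexRecipe(noise_sd=0.0)).atoms[:3]
        traj = TrajectoryEnsemble(coords=coords, atoms=atoms)
        occ = hbond_occupancy(traj, donors=[(0, 1)], acceptors=[2])
        assert occ[0, 0] == 0.0
        loose = HBondCriterion(distance_cutoff=3.5, linearity_deviation=70.0)
        assert hbond_occupancy(traj, [(0, 1)], [2], loose)[0, 0] == 1.0

    def test_exact_fraction_on_scheduled_break(self):
        recipe = fx.DuplexRecipe(noise_sd=0.02, seed=13)
        traj, truth = fx.build_trajectory(
            recipe, 100, events=[fx.BreakHBond(pair_index=1, start=37, stop=100)])
        for (donor, acceptor) in fx.wc_hbond_triplets(traj.atoms, fx.wc_pair(recipe, 1)):
            occ = hbond_occupancy(traj, donors=[donor], acceptors=[acceptor])
            assert occ[0, 0] == 0.37
        assert truth["broken"][1].sum() == 63

    def test_monotone_in_both_cutoffs(self):
        recipe = fx.DuplexRecipe(noise_sd=0.1, seed=17)
        traj, _ = fx.build_trajectory(
            recipe, 60, events=[fx.BreakHBond(pair_index=2, start=20, stop=45,
                                              displacement=0.8)])
        donor, acceptor = fx.wc_hbond_triplets(traj.atoms, fx.wc_pair(recipe, 2))[0]
        prev = -1.0
        for cutoff in (2.0, 2.5, 3.0, 3.5, 4.0, 5.0):
            occ = hbond_occupancy(traj, [donor], [acceptor],
                                  HBondCriterion(distance_cutoff=cutoff))[0, 0]
            assert occ >= prev
            prev = occ
        prev = -1.0
        for dev in (5.0, 15.0, 30.0, 45.0, 60.0, 85.0):
            occ = hbond_occupancy(traj, [donor], [acceptor],
                                  HBondCriterion(linearity_deviation=dev))[0, 0]
            assert occ >= prev
            prev = occ

    def test_empty_lists_error(self):
        traj = self.linear_hbond_traj(2.9)
        with pytest.raises(ValueError, match="non-empty"):
            hbond_occupancy(traj, donors=[], acceptors=[2])

    def test_criterion_validation(self):
        with pytest.raises(ValueError):
            HBondCriterion(distance_cutoff=-1.0)
        with pytest.raises(ValueError):
            HBondCriterion(linearity_deviation=90.0)


def oracle_dihedral(p0, p1, p2, p3):
    """Independent re-derivation: signed angle between bond planes via
    projections onto the plane perpendicular to the central bond."""
    b2 = p2 - p1
    b2 /= np.linalg.norm(b2)
    u = (p0 - p1) - np.dot(p0 - p1, b2) * b2
    v = (p3 - p2) - np.dot(p3 - p2, b2) * b2
    x = np.dot(u, v)
    y = np.dot(np.cross(b2, u), v)
    ang = np.degrees(np.arctan2(y, x))
    return ang + 360.0 if ang <= -180.0 else ang


class TestDihedrals:
    def test_planar_cis_and_trans(self):
        cis = np.array([[1.0, 1, 0], [0, 0, 0], [2, 0, 0], [1.0, 1, 0] + np.array([2.0, 0, 0])])
        cis[3] = [3.0, 1.0, 0.0]
        assert dihedral(cis) == pytest.approx(0.0, abs=1e-10)
        trans = cis.copy()
        trans[3] = [3.0, -1.0, 0.0]
        assert abs(dihedral(trans)) == pytest.approx(180.0, abs=1e-10)

    def test_matches_independent_oracle_on_random_geometries(self, rng):
        for _ in range(20):
            p = rng.uniform(-4, 4, (4, 3))
            assert dihedral(p) == pytest.approx(
                oracle_dihedral(*p), abs=1e-9)

    def test_reversal_symmetry_and_mirror_antisymmetry(self, rng):
        # an IUPAC torsion reads the same from either end of the chain;
        # its sign flips only under an improper operation (mirror reflection)
        for _ in range(10):
            p = rng.uniform(-4, 4, (4, 3))
            fwd = float(dihedral(p))
            assert float(dihedral(p[::-1])) == pytest.approx(fwd, abs=1e-9)
            mirrored = p * np.array([1.0, 1.0, -1.0])
            if abs(abs(fwd) - 180.0) > 1e-6:
                assert float(dihedral(mirrored)) == pytest.approx(-fwd, abs=1e-9)

    def test_series_over_trajectory(self, rng):
        recipe = fx.DuplexRecipe(noise_sd=0.05, seed=19)
        traj, _ = fx.build_trajectory(recipe, 10)
        series = dihedral_series(traj, [0, 2, 8, 14])
        assert series.shape == (10,)
        assert np.all((series > -180.0) & (series <= 180.0))
        with pytest.raises(ValueError, match="distinct"):
            dihedral_series(traj, [0, 0, 1, 2])


class TestTorsionHistogram:
    def test_identical_values_single_bin(self):
        probs, _ = torsion_histogram(np.full(50, 37.0), bin_width=10.0)
        assert probs.max() == 1.0 and probs.sum() == pytest.approx(1.0)

    def test_uniform_draw_matches_flat_distribution(self):
        rng = np.random.default_rng(99)
        draw = rng.uniform(-180.0, 180.0, 100_000)
        probs, _ = torsion_histogram(draw, bin_width=10.0)
        assert len(probs) == 36
        p = 1.0 / 36
        se = np.sqrt(p * (1 - p) / 100_000)
        assert np.all(np.abs(probs - p) < 3 * se + 1e-12)

    def test_probabilities_sum_to_one(self, rng):
        probs, _ = torsion_histogram(rng.uniform(-179, 180, 1234), bin_width=30.0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bin_width_must_divide_360(self):
        with pytest.raises(ValueError, match="divide"):
            torsion_histogram(np.zeros(5), bin_width=7.0)


class TestAtomSelection:
    def test_select_by_residue_and_name(self):
        model = fx.build_duplex(fx.DuplexRecipe(noise_sd=0.0))
        sel = AtomSelection.select(model.atoms, atom_names=["C1"],
                                   residue_indices=range(2, 8))
        assert len(sel) == 6
        assert all(model.atoms[i].atom_name == "C1" for i in sel.indices)

    def test_empty_selection_rejected_when_used(self):
        recipe = fx.DuplexRecipe(noise_sd=0.0)
        traj, _ = fx.build_trajectory(recipe, 3)
        sel = AtomSelection.select(traj.atoms, atom_names=["ZZ"])
        with pytest.raises(ValueError, match="empty"):
            rmsd_series(traj, selection=sel)
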