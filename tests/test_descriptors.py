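"""Superposition, RMSD, Rg, RMSF, helicity and sampling maps."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crowdtraj import (assign_secondary_structure, build_helix,
                       gen_random_coil, kabsch_superpose, radius_of_gyration,
                       rg_series, rmsd_series, rmsf, sampling_map)
from crowdtraj.core import Topology, Trajectory
from crowdtraj.synthetic import _bead_topology


def random_cloud(rng, n=10):
    return rng.normal(size=(n, 3))


class TestKabsch:
    def test_identity_on_equal_clouds(self):
        rng = np.random.default_rng(0)
        x = random_cloud(rng)
        rot, trans, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_recovers_applied_rigid_motion(self):
        rng = np.random.default_rng(1)
        x = random_cloud(rng)
        applied = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = x @ applied.T + np.array([1.0, -2.0, 0.5])
        rot, trans, rmsd = kabsch_superpose(moved, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot, applied.T, atol=1e-8)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            rot, _, _ = kabsch_superpose(random_cloud(rng),
                                         random_cloud(rng))
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_scipy_align_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = random_cloud(rng), random_cloud(rng)
            _, _, rmsd = kabsch_superpose(a, b)
            a0 = a - a.mean(0)
            b0 = b - b.mean(0)
            _, rssd = Rotation.align_vectors(b0, a0)
            assert rmsd == pytest.approx(rssd / np.sqrt(len(a)), abs=1e-9)

    def test_collinear_reference_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_superpose(line + 0.0, line)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_copies_of_reference_are_zero(self, two_state_traj):
        traj, _ = two_state_traj
        ref = traj.xyz[0]
        frames = np.tile(ref, (5, 1, 1))
        t = Trajectory(traj.topology, frames, np.arange(5.0),
                       traj.boxes[:5])
        np.testing.assert_allclose(rmsd_series(t, ref), 0.0, atol=1e-10)

    def test_invariant_to_per_frame_rigid_motion(self, two_state_traj):
        traj, _ = two_state_traj
        sub = Trajectory(traj.topology, traj.xyz[:20].copy(),
                         traj.times[:20], traj.boxes[:20])
        base = rmsd_series(sub, sub.xyz[0])
        rng = np.random.default_rng(5)
        moved = np.array([f @ Rotation.random(rng=rng).as_matrix().T
                          + rng.normal(size=3) for f in sub.xyz])
        t2 = Trajectory(sub.topology, moved, sub.times, sub.boxes)
        np.testing.assert_allclose(rmsd_series(t2, sub.xyz[0]), base,
                                   atol=1e-9)

    def test_two_state_bimodality(self, two_state_traj, two_conformers):
        a, b = two_conformers
        traj, man = two_state_traj
        series = rmsd_series(traj, a)
        _, _, d_ab = kabsch_superpose(b, a)
        states = np.array(man["ground_truth"]["states"])
        assert np.median(series[states == 0]) < 0.1
        assert np.median(series[states == 1]) == pytest.approx(d_ab,
                                                               abs=0.1)


class TestRg:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2, 3]])) == 0.0

    def test_two_equal_masses(self):
        xyz = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(xyz) == pytest.approx(1.0)

    def test_short_helix_more_compact_than_coil(self):
        # rise 0.15 vs bond 0.38: a helical segment is more compact than
        # the coil ensemble only for very short chains (~9 residues), where
        # the ideal-chain sqrt(n) growth still beats the linear helix length
        helix_rg = radius_of_gyration(build_helix(8))
        coil, _ = gen_random_coil(8, n_frames=300, seed=2)
        coil_mean = rg_series(coil).mean()
        assert helix_rg < coil_mean

    def test_long_helix_less_compact_than_coil(self):
        helix_rg = radius_of_gyration(build_helix(50))
        coil, _ = gen_random_coil(50, n_frames=300, seed=3)
        assert helix_rg > rg_series(coil).mean()


class TestRmsf:
    def test_static_trajectory_zero(self):
        top = _bead_topology([5])
        xyz = np.tile(np.random.default_rng(0).normal(size=(5, 3)),
                      (10, 1, 1))
        t = Trajectory(top, xyz, np.arange(10.0),
                       np.array([100.0, 100, 100]))
        np.testing.assert_allclose(rmsf(t), 0.0, atol=1e-12)

    def test_isotropic_noise_gives_sqrt3_sigma(self):
        """Per-coordinate variance sigma^2 gives RMSF -> sqrt(3)*sigma."""
        rng = np.random.default_rng(1)
        sigma = 0.05
        base = rng.normal(size=(100, 3))
        xyz = base + rng.normal(0, sigma, (3000, 100, 3))
        top = _bead_topology([100])
        t = Trajectory(top, xyz, np.arange(3000.0),
                       np.array([1000.0, 1000, 1000]))
        got = rmsf(t)
        # superposition absorbs 6 rigid-body DOF out of 3N, a ~1% bias here
        np.testing.assert_allclose(got, np.sqrt(3) * sigma, rtol=0.05)

    def test_rigid_tumbling_removed_by_superposition(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(12, 3))
        frames = np.array([base @ Rotation.random(rng=rng).as_matrix().T
                           + rng.normal(size=3) for _ in range(50)])
        top = _bead_topology([12])
        t = Trajectory(top, frames, np.arange(50.0),
                       np.array([1000.0, 1000, 1000]))
        assert rmsf(t).max() < 1e-8


class TestSecondaryStructure:
    def test_ideal_helix_interior_fully_helical(self):
        xyz = build_helix(12)
        top = _bead_topology([12])
        t = Trajectory(top, xyz[None], [0.0], np.array([100.0, 100, 100]))
        labels, helicity = assign_secondary_structure(t)
        assert np.all(helicity[:9] == 100.0)

    def test_three_residue_helix_not_assigned(self):
        xyz = build_helix(4)[:3]
        top = _bead_topology([3])
        t = Trajectory(top, xyz[None], [0.0], np.array([100.0, 100, 100]))
        labels, helicity = assign_secondary_structure(t)
        assert np.all(helicity == 0.0)

    def test_coil_has_low_helicity(self):
        traj, _ = gen_random_coil(30, n_frames=1000, seed=9)
        _, helicity = assign_secondary_structure(traj)
        assert np.all(helicity <= 5.0)


class TestSamplingMap:
    def test_constant_series_single_bin(self):
        m = sampling_map(np.ones(50), np.full(50, 2.0), bins=5)
        assert m.counts.sum() == 50
        assert (m.counts > 0).sum() == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(0)
        m = sampling_map(rng.random(1000), rng.random(1000), bins=13)
        assert m.counts.sum() == 1000

    def test_two_state_fixture_two_islands(self, two_state_traj,
                                           two_conformers):
        a, _ = two_conformers
        traj, _ = two_state_traj
        r = rmsd_series(traj, a)
        g = rg_series(traj)
        m = sampling_map(r, g, bins=10, normalize=True)
        # two well-separated occupied regions along the RMSD axis
        occupied_cols = np.flatnonzero(m.counts.sum(axis=1) > 0.01)
        assert occupied_cols.min() <= 2 and occupied_cols.max() >= 7

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sampling_map([], [])
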