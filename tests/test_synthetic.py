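"""Ground-truth generators: reproducibility and planted-truth recovery."""

import numpy as np
import pytest

from crowdtraj import (BrownianSpec, ChainSpec, CrowdedBoxSpec,
                       GaussianEnsembleSpec, HelixPairSpec, TwoStateSpec,
                       build_crowded_box, build_helix, build_helix_pair,
                       gen_brownian, gen_gaussian_ensemble, gen_random_coil,
                       gen_two_state, radius_of_gyration)
from crowdtraj.synthetic import box_edge_for_concentration


class TestBrownian:
    def test_zero_diffusion_is_static(self):
        traj, _ = gen_brownian(BrownianSpec(n_particles=5, d_true=0.0,
                                            n_steps=50, seed=1))
        assert np.all(traj.xyz == traj.xyz[0])

    def test_seed_reproducibility(self):
        a, _ = gen_brownian(BrownianSpec(n_particles=4, n_steps=100, seed=5))
        b, _ = gen_brownian(BrownianSpec(n_particles=4, n_steps=100, seed=5))
        np.testing.assert_array_equal(a.xyz, b.xyz)

    def test_step_variance_matches_2_d_dt(self):
        spec = BrownianSpec(n_particles=200, d_true=5e-4, dt=2.0,
                            n_steps=200, box=(50, 50, 50), seed=2)
        traj, _ = gen_brownian(spec)
        from crowdtraj import unwrapped_com_series
        un = unwrapped_com_series(traj)
        steps = np.diff(un, axis=1)
        assert steps.var() == pytest.approx(2 * spec.d_true * spec.dt,
                                            rel=0.05)

    def test_step_exceeding_half_box_rejected(self):
        with pytest.raises(ValueError, match="half box"):
            BrownianSpec(d_true=10.0, dt=10.0, box=(1, 1, 1))


class TestGaussianEnsemble:
    def test_sample_covariance_converges(self):
        """1-D mode: sample positional variance approaches lambda/m."""
        spec = GaussianEnsembleSpec(eigenvalues=(0.01, 1e-6, 1e-6),
                                    masses=(12.0,) * 3, n_frames=40_000,
                                    seed=3, mix=False)
        traj, _ = gen_gaussian_ensemble(spec)
        flat = traj.xyz.reshape(spec.n_frames, 3) - \
            traj.xyz.reshape(spec.n_frames, 3).mean(axis=0)
        assert flat[:, 0].var() == pytest.approx(0.01 / 12.0, rel=0.05)

    def test_planted_eigenvalues_recovered(self):
        from crowdtraj import mass_weighted_covariance
        ev = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06)
        spec = GaussianEnsembleSpec(eigenvalues=ev, n_frames=60_000, seed=4)
        traj, _ = gen_gaussian_ensemble(spec)
        _, got = mass_weighted_covariance(traj, superpose=False)
        np.testing.assert_allclose(np.sort(got), np.sort(ev), rtol=0.05)

    def test_non_positive_eigenvalue_rejected(self):
        with pytest.raises(ValueError):
            GaussianEnsembleSpec(eigenvalues=(0.01, -1e-3, 0.02))


class TestBuildHelix:
    def test_consecutive_calpha_distance(self):
        xyz = build_helix(10)
        d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
        np.testing.assert_allclose(d, 0.38, atol=0.01)

    def test_i_to_i3_distance_band(self):
        xyz = build_helix(12)
        d = np.linalg.norm(xyz[3:] - xyz[:-3], axis=1)
        assert np.all((d >= 0.49) & (d <= 0.56))

    def test_axis_along_z(self):
        from crowdtraj import helix_vector, HelixDefinition
        from crowdtraj.synthetic import _bead_topology
        xyz = build_helix(10)
        top = _bead_topology([10])
        v = helix_vector(xyz, top, HelixDefinition("h", 0, 9))
        assert np.degrees(np.arccos(abs(v[2]))) < 1.0


class TestHelixPair:
    @pytest.mark.parametrize("el,az", [(0.0, 0.0), (45.0, 90.0),
                                       (-30.0, 120.0)])
    def test_planted_angles_recovered_noiseless(self, el, az):
        from crowdtraj import (HelixDefinition, elevation_azimuth,
                               helix_vector)
        traj, man = build_helix_pair(HelixPairSpec(elevation=el, azimuth=az))
        n = man["spec"]["n_res"]
        v1 = helix_vector(traj.xyz[0], traj.topology,
                          HelixDefinition("h1", 0, n - 1))
        v2 = helix_vector(traj.xyz[0], traj.topology,
                          HelixDefinition("h2", n, 2 * n - 1))
        got_el, got_az, _ = elevation_azimuth(
            v1, man["ground_truth"]["frame_plane"], v2)
        assert got_el == pytest.approx(el, abs=1.0)
        if abs(el) < 89:
            assert abs((got_az - az + 180) % 360 - 180) < 1.0

    def test_invalid_angles_rejected(self):
        with pytest.raises(ValueError):
            HelixPairSpec(elevation=120.0)


class TestRandomCoil:
    def test_bond_lengths_exact(self):
        traj, _ = gen_random_coil(20, n_frames=5, seed=1)
        for f in range(5):
            d = np.linalg.norm(np.diff(traj.xyz[f], axis=0), axis=1)
            np.testing.assert_allclose(d, 0.38, atol=1e-12)

    def test_two_residue_rg(self):
        traj, _ = gen_random_coil(2, n_frames=1, seed=0)
        assert radius_of_gyration(traj.xyz[0]) == pytest.approx(0.19)

    def test_ideal_chain_rg_scaling(self):
        """Mean Rg grows like sqrt(n) for a freely jointed chain."""
        means = []
        for n in (25, 100):
            traj, _ = gen_random_coil(n, n_frames=300, seed=n)
            means.append(np.mean([radius_of_gyration(traj.xyz[f])
                                  for f in range(300)]))
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.15)

    def test_planted_pair_within_cutoff(self):
        traj, man = gen_random_coil(50, n_frames=200, seed=6,
                                    planted_contact_pairs=[(5, 40)])
        d = np.linalg.norm(traj.xyz[:, 5] - traj.xyz[:, 40], axis=1)
        assert np.mean(d <= 0.8) >= 0.95

    def test_overlapping_planted_intervals_rejected(self):
        with pytest.raises(ValueError, match="[Oo]verlapping"):
            gen_random_coil(50, planted_contact_pairs=[(5, 30), (20, 45)])

    def test_close_pair_rejected(self):
        with pytest.raises(ValueError, match="3 residues"):
            gen_random_coil(50, planted_contact_pairs=[(5, 7)])


class TestTwoState:
    def test_no_switch_when_dwell_equals_length(self, two_conformers):
        a, b = two_conformers
        spec = TwoStateSpec(conformer_a=a, conformer_b=b,
                            mean_dwell=1e12, n_frames=100, seed=1)
        _, man = gen_two_state(spec)
        assert man["ground_truth"]["n_transitions"] == 0

    def test_zero_noise_clusters_reproduce_states(self, two_conformers):
        from crowdtraj import gromos_cluster
        a, b = two_conformers
        spec = TwoStateSpec(conformer_a=a, conformer_b=b, mean_dwell=20,
                            noise_sigma=0.0, n_frames=200, seed=2)
        traj, man = gen_two_state(spec)
        assign = gromos_cluster(traj, cutoff=0.15)
        states = np.array(man["ground_truth"]["states"])
        # labels are a relabeling of the hidden states
        for k in np.unique(assign.labels):
            assert len(np.unique(states[assign.labels == k])) == 1

    def test_similar_conformers_rejected(self, two_conformers):
        a, _ = two_conformers
        with pytest.raises(ValueError, match="too similar"):
            TwoStateSpec(conformer_a=a, conformer_b=a + 1e-4)


class TestCrowdedBox:
    def test_unit_arithmetic_oracle(self):
        # 6022 amu ~ 1e-20 g; at 100 g/L the volume is 1e-22 L = 100 nm^3
        assert box_edge_for_concentration(6022.0, 100.0) == pytest.approx(
            4.6416, abs=0.001)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            CrowdedBoxSpec(concentration=0.0)

    def test_achieved_concentration_within_2pct(self):
        spec = CrowdedBoxSpec(chains=(ChainSpec(30, "coil", 4),
                                      ChainSpec(20, "helix", 4)),
                              concentration=192.0, seed=11)
        _, man = build_crowded_box(spec)
        achieved = man["ground_truth"]["achieved_concentration_g_per_l"]
        assert abs(achieved - 192.0) / 192.0 < 0.02

    def test_no_clashes_in_first_frame(self):
        from scipy.spatial import cKDTree
        spec = CrowdedBoxSpec(concentration=150.0, seed=3)
        traj, man = build_crowded_box(spec)
        tree = cKDTree(traj.xyz[0], boxsize=traj.boxes[0])
        pairs = tree.query_pairs(0.299)
        starts = np.cumsum([0] + man["ground_truth"]["chain_lengths"][:-1])
        chain_of = np.searchsorted(starts, np.arange(traj.n_atoms),
                                   side="right") - 1
        inter = [p for p in pairs if chain_of[p[0]] != chain_of[p[1]]]
        assert not inter

    def test_determinism(self):
        spec = CrowdedBoxSpec(concentration=100.0, n_frames=3, seed=5)
        a, _ = build_crowded_box(spec)
        b, _ = build_crowded_box(spec)
        np.testing.assert_array_equal(a.xyz, b.xyz)
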