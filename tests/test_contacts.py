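"""Calpha contact maps, explored contacts, quinary composition, overlap."""

import numpy as np
import pytest

from crowdtraj import (ContactMap, class_composition, contact_difference,
                       contact_map, explored_contacts, gen_random_coil,
                       interprotein_fraction, native_overlap, wrap_into_box)
from crowdtraj.core import Trajectory
from crowdtraj.synthetic import _bead_topology


def straight_chain_traj(n_res=10, spacing=0.38, n_frames=1, n_chains=1,
                        chain_offset=5.0, box=100.0):
    """Extended chains along x, optionally several chains offset in y."""
    chains = []
    for c in range(n_chains):
        xyz = np.column_stack([spacing * np.arange(n_res),
                               np.full(n_res, c * chain_offset),
                               np.zeros(n_res)])
        chains.append(xyz)
    frame = np.vstack(chains)
    top = _bead_topology([n_res] * n_chains)
    frames = np.tile(frame, (n_frames, 1, 1))
    return Trajectory(top, frames, np.arange(float(n_frames)) * 20.0,
                      np.array([box] * 3))


class TestContactMap:
    def test_planted_pair_occupancy(self):
        traj, _ = gen_random_coil(50, n_frames=150, seed=3,
                                  planted_contact_pairs=[(5, 40)])
        cmap = contact_map(traj, range(50))
        assert cmap.occupancy[5, 40] >= 0.95

    def test_distant_chains_all_zero(self):
        traj = straight_chain_traj(n_chains=2, chain_offset=10.0,
                                   n_frames=3)
        cmap = contact_map(traj, range(10), range(10, 20))
        assert np.all(cmap.occupancy == 0.0)

    def test_intra_map_symmetric(self):
        traj, _ = gen_random_coil(30, n_frames=50, seed=1)
        cmap = contact_map(traj, range(30))
        np.testing.assert_array_equal(cmap.occupancy, cmap.occupancy.T)

    def test_pbc_invariance_under_rewrapping(self):
        """A chain straddling the boundary gives the same map as its
        unwrapped copy."""
        traj, _ = gen_random_coil(20, n_frames=30, seed=5)
        box = np.array([6.0, 6.0, 6.0])
        shifted = traj.xyz + np.array([5.9, 0, 0])  # straddles +x face
        wrapped = wrap_into_box(shifted, box)
        t_un = Trajectory(traj.topology, shifted, traj.times,
                          np.tile(box, (traj.n_frames, 1)))
        t_wr = Trajectory(traj.topology, wrapped, traj.times,
                          np.tile(box, (traj.n_frames, 1)))
        np.testing.assert_allclose(
            contact_map(t_un, range(20)).occupancy,
            contact_map(t_wr, range(20)).occupancy)

    def test_occupancy_monotone_in_cutoff(self):
        traj, _ = gen_random_coil(25, n_frames=40, seed=8)
        occ_small = contact_map(traj, range(25), cutoff=0.6).occupancy
        occ_large = contact_map(traj, range(25), cutoff=1.0).occupancy
        assert np.all(occ_large >= occ_small)

    def test_overlapping_groups_rejected(self):
        traj = straight_chain_traj()
        with pytest.raises(ValueError, match="disjoint"):
            contact_map(traj, range(5), range(4, 8))


class TestExploredContacts:
    def make_traj_with_contact_frames(self, n_contact_frames):
        """Pair (0, 5) in contact for exactly the requested frame count."""
        n_res, n_frames = 8, 12
        near = np.column_stack([0.2 * np.arange(n_res), np.zeros(n_res),
                                np.zeros(n_res)])  # d(0,5)=1.0 > 0.8? 0.2*5=1.0
        near[5] = [0.5, 0, 0]                      # d(0,5)=0.5: contact
        far = near.copy()
        far[5] = [3.0, 3.0, 0]                     # no contact
        frames = np.array([near if f < n_contact_frames else far
                           for f in range(n_frames)])
        top = _bead_topology([n_res])
        return Trajectory(top, frames, np.arange(float(n_frames)),
                          np.array([100.0] * 3))

    def test_exactly_five_frames_not_explored(self):
        traj = self.make_traj_with_contact_frames(5)
        cmap = contact_map(traj, range(8))
        assert cmap.counts[0, 5] == 5
        count, _ = explored_contacts(traj, range(8), cmap=cmap)
        # pair (0,5) sits at the threshold boundary: excluded
        explored_pairs = (cmap.counts > 5)
        assert not explored_pairs[0, 5]

    def test_six_frames_explored(self):
        traj = self.make_traj_with_contact_frames(6)
        cmap = contact_map(traj, range(8))
        assert cmap.counts[0, 5] == 6
        assert (cmap.counts > 5)[0, 5]

    def test_monotone_in_trajectory_length(self):
        traj, _ = gen_random_coil(30, n_frames=120, seed=2)
        counts = []
        for n in (30, 60, 120):
            sub = Trajectory(traj.topology, traj.xyz[:n], traj.times[:n],
                             traj.boxes[:n])
            counts.append(explored_contacts(sub, range(30))[0])
        assert counts[0] <= counts[1] <= counts[2]

    def test_union_exceeds_single_frame_fraction(self):
        traj, _ = gen_random_coil(40, n_frames=100, seed=4)
        _, frac = explored_contacts(traj, range(40), min_frames=0)
        single = contact_map(
            Trajectory(traj.topology, traj.xyz[:1], traj.times[:1],
                       traj.boxes[:1]), range(40))
        from crowdtraj.contacts import _intra_pair_mask
        mask = _intra_pair_mask(single)
        single_frac = (single.counts[mask] > 0).mean()
        assert frac > single_frac


class TestInterproteinFraction:
    def test_isolated_chain_zero(self):
        traj, _ = gen_random_coil(20, n_frames=10, seed=1)
        assert interprotein_fraction(traj, range(20), []) == 0.0

    def test_interdigitated_extended_chains_100pct(self):
        # two parallel extended chains 0.5 nm apart: only inter contacts
        traj = straight_chain_traj(n_res=10, n_chains=2, chain_offset=0.5,
                                   n_frames=4)
        pct = interprotein_fraction(traj, range(10), range(10, 20))
        assert pct == pytest.approx(100.0)

    def test_matches_brute_force_event_recount(self):
        from crowdtraj import CrowdedBoxSpec, build_crowded_box
        traj, man = build_crowded_box(
            CrowdedBoxSpec(concentration=250.0, n_frames=10, seed=13))
        lengths = man["ground_truth"]["chain_lengths"]
        chain0 = list(range(lengths[0]))
        others = list(range(lengths[0], sum(lengths)))
        got = interprotein_fraction(traj, chain0, others)
        # independent recount from raw minimum-image distances
        from crowdtraj.core import minimum_image_displacement
        ca = traj.xyz
        per_frame = []
        for f in range(traj.n_frames):
            box = traj.boxes[f]
            inter = intra = 0
            for i in chain0:
                for j in others:
                    d = np.linalg.norm(minimum_image_displacement(
                        ca[f, i], ca[f, j], box))
                    inter += d <= 0.8
                for j in chain0:
                    if j - i > 2:
                        d = np.linalg.norm(minimum_image_displacement(
                            ca[f, i], ca[f, j], box))
                        intra += d <= 0.8
            if inter + intra:
                per_frame.append(100.0 * inter / (inter + intra))
        assert got == pytest.approx(np.mean(per_frame), abs=1e-9)


class TestClassComposition:
    def test_all_ala_chain_is_hydrophobic(self):
        traj, _ = gen_random_coil(20, n_frames=20, seed=6)
        cmap = contact_map(traj, range(20))
        comp = class_composition(cmap, ["ALA"] * 20)
        assert comp.contact_shares["H"] == pytest.approx(100.0)
        assert comp.background_shares["H"] == pytest.approx(100.0)

    def test_zero_contacts_flagged(self):
        traj = straight_chain_traj(n_chains=2, chain_offset=10.0)
        cmap = contact_map(traj, range(10), range(10, 20))
        comp = class_composition(cmap, ["ALA"] * 10)
        assert comp.no_contacts

    def test_planted_charged_pair_dominates(self):
        traj, _ = gen_random_coil(50, n_frames=100, seed=7,
                                  planted_contact_pairs=[(10, 40)])
        names = ["GLY"] * 50
        names[10], names[40] = "LYS", "GLU"
        cmap = contact_map(traj, range(50))
        # keep only the planted cell to mimic an occupancy-dominant pair
        occ = np.zeros_like(cmap.occupancy)
        occ[10, 40] = occ[40, 10] = cmap.occupancy[10, 40]
        cmap2 = ContactMap(cmap.residues_a, cmap.residues_b, occ,
                           (occ * cmap.n_frames).astype(int), cmap.cutoff,
                           cmap.n_frames, True)
        comp = class_composition(cmap2, names)
        assert comp.contact_shares["C"] == pytest.approx(100.0)

    def test_nonstandard_residue_reported_as_u(self):
        traj, _ = gen_random_coil(10, n_frames=10, seed=1)
        cmap = contact_map(traj, range(10))
        comp = class_composition(cmap, ["XYZ"] * 10)
        assert comp.contact_shares["U"] == pytest.approx(100.0)


class TestDifferenceAndOverlap:
    def test_difference_zero_and_antisymmetric(self):
        traj, _ = gen_random_coil(20, n_frames=30, seed=2)
        a = contact_map(traj, range(20))
        assert np.all(contact_difference(a, a) == 0.0)
        traj2, _ = gen_random_coil(20, n_frames=30, seed=3)
        b = contact_map(traj2, range(20))
        np.testing.assert_array_equal(contact_difference(a, b),
                                      -contact_difference(b, a))

    def test_planted_contact_shows_in_difference(self):
        with_pair, _ = gen_random_coil(40, n_frames=100, seed=4,
                                       planted_contact_pairs=[(5, 30)])
        without, _ = gen_random_coil(40, n_frames=100, seed=4)
        diff = contact_difference(contact_map(with_pair, range(40)),
                                  contact_map(without, range(40)))
        assert diff[5, 30] > 0.8

    def test_shape_mismatch_rejected(self):
        t1, _ = gen_random_coil(10, n_frames=5, seed=0)
        t2, _ = gen_random_coil(12, n_frames=5, seed=0)
        with pytest.raises(ValueError):
            contact_difference(contact_map(t1, range(10)),
                               contact_map(t2, range(12)))

    def test_frozen_reference_full_overlap(self):
        ref, _ = gen_random_coil(25, n_frames=1, seed=9)
        frames = np.tile(ref.xyz[0], (10, 1, 1))
        frozen = Trajectory(ref.topology, frames, np.arange(10.0),
                            np.tile(ref.boxes[0], (10, 1)))
        cmap = contact_map(frozen, range(25))
        assert native_overlap(cmap, ref, range(25),
                              occupancy_threshold=0.9) == 1.0

    def test_half_occupancy_thresholds(self, two_state_traj,
                                       two_conformers):
        """State A = reference; its contacts hold ~50% of the time, so the
        overlap flips between thresholds below and above 0.5."""
        a, _ = two_conformers
        traj, man = two_state_traj
        ref = Trajectory(traj.topology, a[None], [0.0],
                         np.array([1000.0] * 3))
        cmap = contact_map(traj, range(15))
        hi = native_overlap(cmap, ref, range(15), occupancy_threshold=0.25)
        lo = native_overlap(cmap, ref, range(15), occupancy_threshold=0.75)
        assert hi == pytest.approx(1.0)
        assert lo == pytest.approx(0.0, abs=0.2)
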