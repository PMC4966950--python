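"""Calpha contact analysis: occupancy maps, explored-contact statistics,
quinary (inter-protein) contact composition, native-contact overlap and
environment difference maps.

A contact is a Calpha pair within 0.8 nm; inter-molecular distances use the
minimum image in the frame's periodic box.  Intra-chain statistics exclude
sequence neighbors |i - j| <= 2, which would otherwise swamp the counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory, minimum_image_displacement
from .constants import DEFAULT_RESIDUE_CLASSES

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.8       # nm, Calpha-Calpha
NEIGHBOR_EXCLUSION = 2     # |i-j| <= 2 excluded from intra statistics
EXPLORED_MIN_FRAMES = 5    # "explored" means found in MORE than this


@dataclass
class ContactMap:
    """Residue-pair occupancy map (fraction of frames within the cutoff)."""

    residues_a: np.ndarray     # global residue indices, rows
    residues_b: np.ndarray     # columns
    occupancy: np.ndarray      # (len_a, len_b) in [0, 1]
    counts: np.ndarray         # raw frame counts
    cutoff: float
    n_frames: int
    intra: bool
    pbc: bool = True

    def __post_init__(self) -> None:
        if np.any(self.occupancy < 0) or np.any(self.occupancy > 1):
            raise ValueError("occupancy must lie in [0, 1]")

    def to_long_dataframe(self):
        """Long-format (i, j, occupancy) table, 1-based residue numbers."""
        import pandas as pd
        ii, jj = np.meshgrid(self.residues_a, self.residues_b, indexing="ij")
        return pd.DataFrame({"i": ii.ravel() + 1, "j": jj.ravel() + 1,
                             "occupancy": self.occupancy.ravel()})


def _calpha_coords(traj: Trajectory, residues) -> tuple[np.ndarray, np.ndarray]:
    """(n_frames, n_res, 3) Calpha positions for the residues, dropping (with
    a warning) residues that have no Calpha."""
    top = traj.topology
    keep, rows = [], []
    for r in residues:
        hit = np.flatnonzero((top.residue_indices == r) & (top.names == "CA"))
        if len(hit) == 0:
            log.warning("residue %d has no Calpha; dropped", r + 1)
            continue
        keep.append(r)
        rows.append(hit[0])
    return np.asarray(keep, int), traj.xyz[:, rows, :]


def contact_map(traj: Trajectory, group_a, group_b=None,
                cutoff: float = DEFAULT_CUTOFF, pbc: bool = True
                ) -> ContactMap:
    """Occupancy map between two residue groups (intra when ``group_b`` is
    omitted or equals ``group_a``).

    occupancy(i, j) = (# frames with min-image d_Ca(i,j) <= cutoff) / n_frames
    """
    group_a = np.asarray(sorted(group_a), int)
    intra = group_b is None or np.array_equal(
        np.sort(np.asarray(group_b)), group_a)
    group_b_arr = group_a if intra else np.asarray(sorted(group_b), int)
    if not intra and len(np.intersect1d(group_a, group_b_arr)):
        raise ValueError("inter-group contact map requires disjoint groups")

    res_a, ca_a = _calpha_coords(traj, group_a)
    res_b, ca_b = (res_a, ca_a) if intra else _calpha_coords(traj, group_b_arr)
    counts = np.zeros((len(res_a), len(res_b)), dtype=int)
    for f in range(traj.n_frames):
        if pbc:
            d = np.linalg.norm(minimum_image_displacement(
                ca_a[f][:, None, :], ca_b[f][None, :, :], traj.boxes[f]),
                axis=-1)
        else:
            d = np.linalg.norm(ca_a[f][:, None, :] - ca_b[f][None, :, :],
                               axis=-1)
        counts += d <= cutoff
    occ = counts / traj.n_frames
    return ContactMap(res_a, res_b, occ, counts, cutoff, traj.n_frames,
                      intra, pbc)


def _intra_pair_mask(cmap: ContactMap) -> np.ndarray:
    """Upper-triangle pairs with the sequence-neighbor exclusion applied."""
    ii, jj = np.meshgrid(cmap.residues_a, cmap.residues_b, indexing="ij")
    return (jj - ii) > NEIGHBOR_EXCLUSION


def explored_contacts(traj: Trajectory, group, cutoff: float = DEFAULT_CUTOFF,
                      min_frames: int = EXPLORED_MIN_FRAMES,
                      cmap: ContactMap | None = None
                      ) -> tuple[int, float]:
    """Count of intra-group pairs found in contact in MORE than
    ``min_frames`` frames (strict), and the fraction of all eligible pairs.

    Eligible pairs exclude sequence neighbors |i - j| <= 2.
    """
    if cmap is None:
        cmap = contact_map(traj, group, cutoff=cutoff)
    mask = _intra_pair_mask(cmap)
    explored = (cmap.counts > min_frames) & mask
    n_possible = int(mask.sum())
    count = int(explored.sum())
    return count, count / n_possible if n_possible else 0.0


def interprotein_fraction(traj: Trajectory, chain_residues, other_residues,
                          cutoff: float = DEFAULT_CUTOFF) -> float:
    """Percentage of a chain's instantaneous contacts that are
    inter-protein, averaged over frames.

    Per frame: 100 * inter events / (inter + intra events); frames with no
    contacts at all are skipped (and logged).
    """
    chain = np.asarray(sorted(chain_residues), int)
    other = np.asarray(sorted(other_residues), int)
    _, ca_c = _calpha_coords(traj, chain)
    _, ca_o = _calpha_coords(traj, other)
    res_c, _ = _calpha_coords(traj, chain)
    ii, jj = np.meshgrid(res_c, res_c, indexing="ij")
    intra_mask = (jj - ii) > NEIGHBOR_EXCLUSION
    fracs = []
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        d_ii = np.linalg.norm(minimum_image_displacement(
            ca_c[f][:, None], ca_c[f][None, :], box), axis=-1)
        intra = int(((d_ii <= cutoff) & intra_mask).sum())
        d_io = np.linalg.norm(minimum_image_displacement(
            ca_c[f][:, None], ca_o[f][None, :], box), axis=-1)
        inter = int((d_io <= cutoff).sum())
        if intra + inter == 0:
            log.info("frame %d has no contacts; skipped", f)
            continue
        fracs.append(100.0 * inter / (inter + intra))
    if not fracs:
        return 0.0
    return float(np.mean(fracs))


@dataclass
class ClassComposition:
    """Occupancy-weighted class shares of contacting residues vs the chain's
    background sequence composition (percent per class)."""

    contact_shares: dict = field(default_factory=dict)   # {H,P,C,U} -> %
    background_shares: dict = field(default_factory=dict)
    no_contacts: bool = False


def class_composition(cmap: ContactMap, residue_names_a,
                      scheme: dict | None = None,
                      sequence_names=None) -> ClassComposition:
    """Distribution over {H, P, C} of the group-A residues engaged in the
    map's contacts, each contact weighted by its occupancy.

    ``residue_names_a``: 3-letter code per group-A residue (map row order).
    ``sequence_names`` (default = residue_names_a) sets the background
    composition of the chain.  Nonstandard residues report as class U.
    """
    scheme = dict(DEFAULT_RESIDUE_CLASSES if scheme is None else scheme)
    names = list(residue_names_a)
    if len(names) != len(cmap.residues_a):
        raise ValueError("one residue name per group-A residue required")
    weights = cmap.occupancy.sum(axis=1)
    shares = {"H": 0.0, "P": 0.0, "C": 0.0, "U": 0.0}
    total = weights.sum()
    if total == 0:
        comp = ClassComposition(no_contacts=True)
    else:
        for w, nm in zip(weights, names):
            shares[scheme.get(str(nm).upper(), "U")] += w
        comp = ClassComposition(
            {k: 100.0 * v / total for k, v in shares.items()})
    seq = list(sequence_names) if sequence_names is not None else names
    bg = {"H": 0.0, "P": 0.0, "C": 0.0, "U": 0.0}
    for nm in seq:
        bg[scheme.get(str(nm).upper(), "U")] += 1
    comp.background_shares = {k: 100.0 * v / len(seq) for k, v in bg.items()}
    return comp


def contact_difference(map_a: ContactMap, map_b: ContactMap) -> np.ndarray:
    """Signed occupancy difference A - B (e.g. water minus crowded)."""
    if map_a.occupancy.shape != map_b.occupancy.shape or \
            not np.array_equal(map_a.residues_a, map_b.residues_a) or \
            not np.array_equal(map_a.residues_b, map_b.residues_b):
        raise ValueError("contact maps must share residue indexing")
    return map_a.occupancy - map_b.occupancy


def native_overlap(cmap: ContactMap, reference_traj: Trajectory,
                   group_a, group_b=None, cutoff: float | None = None,
                   occupancy_threshold: float = 0.5) -> float:
    """Fraction of reference-structure contacts that the trajectory
    maintains with occupancy above ``occupancy_threshold``.

    The reference contact set is computed from the (single-frame) reference
    at the same cutoff.  Returns a value in [0, 1]; 1.0 when the reference
    has no contacts at all (nothing to lose).
    """
    cutoff = cmap.cutoff if cutoff is None else cutoff
    ref_map = contact_map(reference_traj, group_a, group_b, cutoff=cutoff)
    if not (np.array_equal(ref_map.residues_a, cmap.residues_a) and
            np.array_equal(ref_map.residues_b, cmap.residues_b)):
        missing = np.setxor1d(ref_map.residues_a, cmap.residues_a)
        raise ValueError(
            f"residue numbering mismatch with reference: {missing + 1}")
    native = ref_map.counts > 0
    if cmap.intra:
        native &= _intra_pair_mask(cmap)
    n_native = int(native.sum())
    if n_native == 0:
        return 1.0
    kept = int(((cmap.occupancy > occupancy_threshold) & native).sum())
    return kept / n_native
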