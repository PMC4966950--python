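"""Core in-memory containers: Topology, Trajectory, Selection, and the
orthorhombic periodic-boundary utilities every analysis module relies on.

Units are fixed package-wide: coordinates in nm, times in ps, masses in amu.
Residue indices are 0-based internally; report emitters convert to 1-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Molecule:
    """One covalently contiguous molecule (a chain, a crowder copy, a water)."""

    molecule_id: int
    first_residue: int  # 0-based, inclusive
    last_residue: int   # 0-based, inclusive
    label: str = ""


@dataclass
class Topology:
    """Static half of a system: atom identities, residues, molecules.

    All per-atom fields are parallel arrays of length ``n_atoms``.
    """

    names: np.ndarray          # atom names, str
    elements: np.ndarray       # element symbols, str
    masses: np.ndarray         # amu, float
    residue_indices: np.ndarray  # 0-based global residue index, int
    residue_names: np.ndarray  # 3-letter codes, str
    molecule_ids: np.ndarray   # int
    molecules: list[Molecule] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if np.any(self.masses <= 0):
            raise ValueError("all atom masses must be > 0")
        n = len(self.names)
        for arr in (self.elements, self.masses, self.residue_indices,
                    self.residue_names, self.molecule_ids):
            if len(arr) != n:
                raise ValueError("topology per-atom arrays must share length")
        # residue indices non-decreasing within each molecule
        for mol_id in np.unique(self.molecule_ids):
            res = self.residue_indices[self.molecule_ids == mol_id]
            if np.any(np.diff(res) < 0):
                raise ValueError(
                    f"residue indices decrease within molecule {mol_id}")
        if not self.molecules:
            self.molecules = [
                Molecule(int(m),
                         int(self.residue_indices[self.molecule_ids == m].min()),
                         int(self.residue_indices[self.molecule_ids == m].max()))
                for m in np.unique(self.molecule_ids)
            ]

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.residue_indices))

    @property
    def is_backbone(self) -> np.ndarray:
        from .constants import BACKBONE_ATOM_NAMES
        return np.array([n in BACKBONE_ATOM_NAMES for n in self.names])

    @property
    def is_sidechain(self) -> np.ndarray:
        return ~self.is_backbone

    # ---- selections -------------------------------------------------
    def select(self, *, names=None, molecule_id=None, backbone=None,
               label: str = "") -> "Selection":
        """Boolean AND of the given criteria; returns atom indices."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if names is not None:
            names = set(names)
            mask &= np.array([n in names for n in self.names])
        if molecule_id is not None:
            mask &= self.molecule_ids == molecule_id
        if backbone is not None:
            mask &= self.is_backbone if backbone else self.is_sidechain
        return Selection(np.flatnonzero(mask), label=label)

    def calpha(self, molecule_id: int | None = None) -> "Selection":
        return self.select(names=["CA"], molecule_id=molecule_id, label="CA")


@dataclass
class Selection:
    """A set of atom indices with a human-readable label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Trajectory:
    """Per-frame positions bound to a Topology.

    ``xyz``: (n_frames, n_atoms, 3) nm; ``times``: (n_frames,) ps;
    ``boxes``: (n_frames, 3) orthorhombic box edges in nm.
    """

    topology: Topology
    xyz: np.ndarray
    times: np.ndarray
    boxes: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError("xyz must have shape (n_frames, n_atoms, 3)")
        if self.xyz.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.xyz.shape[1]} != topology "
                f"{self.topology.n_atoms}")
        if self.boxes.ndim == 1:
            self.boxes = np.tile(self.boxes, (self.n_frames, 1))
        if len(self.times) != self.n_frames or len(self.boxes) != self.n_frames:
            raise ValueError("times/boxes length must match n_frames")
        if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.boxes <= 0):
            raise ValueError("box lengths must be > 0")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.xyz.shape[1]

    @property
    def dt(self) -> float:
        """Frame spacing in ps (assumes uniform sampling)."""
        if self.n_frames < 2:
            raise ValueError("dt undefined for a single frame")
        return float(self.times[1] - self.times[0])

    def com_series(self, selection: Selection | None = None,
                   per_molecule: bool = False) -> np.ndarray:
        """Mass-weighted center-of-mass series.

        Returns (n_frames, 3) or, with ``per_molecule``, a
        (n_molecules, n_frames, 3) array ordered by molecule id.
        """
        if per_molecule:
            out = []
            for mol in self.topology.molecules:
                sel = self.topology.select(molecule_id=mol.molecule_id)
                out.append(self.com_series(sel))
            return np.array(out)
        idx = (selection.indices if selection is not None
               else np.arange(self.n_atoms))
        m = self.topology.masses[idx]
        return np.einsum("fij,i->fj", self.xyz[:, idx, :], m) / m.sum()

    def slice_atoms(self, selection: Selection) -> "Trajectory":
        idx = selection.indices
        top = Topology(self.topology.names[idx], self.topology.elements[idx],
                       self.topology.masses[idx],
                       self.topology.residue_indices[idx],
                       self.topology.residue_names[idx],
                       self.topology.molecule_ids[idx])
        return Trajectory(top, self.xyz[:, idx, :], self.times, self.boxes)


# ---------------------------------------------------------------------------
# periodic-boundary utilities (orthorhombic only)
# ---------------------------------------------------------------------------

def _check_box(box: np.ndarray) -> np.ndarray:
    box = np.asarray(box, dtype=float)
    if box.shape[-1] != 3 or np.any(box <= 0):
        raise ValueError("box must be three positive edge lengths (nm)")
    return box


def minimum_image_displacement(p1, p2, box) -> np.ndarray:
    """Minimum-image displacement vector(s) p2 - p1 in an orthorhombic box."""
    box = _check_box(box)
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    return d - box * np.round(d / box)


def minimum_image_distance(p1, p2, box) -> float | np.ndarray:
    """Minimum distance between points over all periodic images.

    Accepts single points or broadcastable arrays of points; the result is
    never larger than half the box diagonal.
    """
    d = minimum_image_displacement(p1, p2, box)
    return np.linalg.norm(d, axis=-1)


def wrap_into_box(xyz: np.ndarray, box) -> np.ndarray:
    """Wrap coordinates into [0, L) per axis.

    ``np.mod`` can round a tiny negative coordinate to exactly L; such
    values are folded back to 0 so the half-open interval contract holds.
    """
    box = _check_box(box)
    out = np.mod(xyz, box)
    return np.where(out >= box, out - box, out)


def unwrap(series: np.ndarray, boxes: np.ndarray) -> np.ndarray:
    """Remove periodic jumps from a wrapped coordinate series.

    ``series``: (n_frames, ..., 3) wrapped coordinates; ``boxes``:
    (n_frames, 3) per-frame box edges.  Assumes the true displacement
    between consecutive frames is below half a box edge per axis; if the
    wrapped displacement ever reaches half a box a warning names the frame
    (the unwrap is then ambiguous).
    """
    series = np.asarray(series, dtype=float)
    boxes = _check_box(np.asarray(boxes, dtype=float))
    if len(series) < 2:
        return series.copy()
    d = np.diff(series, axis=0)
    box_b = boxes[1:].reshape((len(series) - 1,)
                              + (1,) * (series.ndim - 2) + (3,))
    near_half = np.abs(np.abs(d) - box_b / 2) < 1e-9
    if np.any(near_half):
        frame = int(np.argwhere(near_half.reshape(len(d), -1).any(axis=1))[0])
        warnings.warn(
            f"displacement at frame {frame + 1} is half a box edge; "
            "unwrap is ambiguous (sampling too coarse?)")
    shifts = -np.cumsum(np.round(d / box_b) * box_b, axis=0)
    out = series.copy()
    out[1:] += shifts
    return out


def unwrapped_com_series(traj: Trajectory, per_molecule: bool = True
                         ) -> np.ndarray:
    """Continuous (unwrapped) center-of-mass series per molecule.

    Centers of mass are computed from wrapped coordinates per frame, then the
    COM series itself is unwrapped.  Valid while each molecule stays compact
    relative to the box (true for the chain sizes this package generates).
    """
    coms = traj.com_series(per_molecule=True)  # (n_mol, n_frames, 3)
    out = unwrap(coms.transpose(1, 0, 2), traj.boxes).transpose(1, 0, 2)
    return out if per_molecule else out.mean(axis=0)
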