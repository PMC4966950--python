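"""Structure and trajectory readers/writers (PDB, GRO, XTC).

MDAnalysis does the format work; everything is converted to package units
(nm, ps) on ingest and back to the format's native units on write.  Only
orthorhombic boxes are supported — triclinic input raises immediately.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .core import Molecule, Topology, Trajectory
from .constants import ELEMENT_MASSES, FALLBACK_MASS_AMU

_A_TO_NM = 0.1
_NM_TO_A = 10.0

_TWO_LETTER = {"CL", "BR", "SE", "NA", "MG", "ZN", "FE", "CA", "MN", "CU"}


def _infer_element(name: str) -> str:
    """Element from an atom name (PDB conventions, no element column)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    two = stripped[:2].upper()
    # amino-acid CA is carbon, not calcium; only trust 2-letter symbols for
    # names that are exactly the symbol (ions / halogens)
    if two in _TWO_LETTER and stripped.upper() == two:
        return two
    return stripped[0].upper()


def _check_orthorhombic(dimensions) -> np.ndarray:
    if dimensions is None or np.all(np.asarray(dimensions)[:3] == 0):
        # structure files often carry no box; use a generous dummy
        return np.array([1000.0, 1000.0, 1000.0])
    dims = np.asarray(dimensions, dtype=float)
    if len(dims) >= 6 and not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise ValueError(
            f"triclinic box (angles {dims[3:6]}) is unsupported; "
            "only orthorhombic boxes are handled")
    return dims[:3] * _A_TO_NM


def _topology_from_universe(u, molecule_map=None) -> Topology:
    n = len(u.atoms)
    names = np.array([a.name for a in u.atoms], dtype=object)
    try:
        elements = np.array(
            [e if e else _infer_element(nm)
             for e, nm in zip(u.atoms.elements, names)], dtype=object)
    except Exception:
        elements = np.array([_infer_element(nm) for nm in names], dtype=object)
        warnings.warn("no element records; elements inferred from atom names")
    try:
        masses = np.asarray(u.atoms.masses, dtype=float)
        if np.any(masses <= 0):
            raise ValueError
    except Exception:
        masses = np.array([ELEMENT_MASSES.get(e, FALLBACK_MASS_AMU)
                           for e in elements])
    masses = np.where(masses > 0, masses,
                      [ELEMENT_MASSES.get(e, FALLBACK_MASS_AMU)
                       for e in elements])

    # global 0-based residue index in file order
    resmap: dict = {}
    residue_indices = np.empty(n, dtype=int)
    residue_names = np.empty(n, dtype=object)
    for i, a in enumerate(u.atoms):
        key = (a.segid, getattr(a, "chainID", ""), a.resid, a.resname)
        if key not in resmap:
            resmap[key] = len(resmap)
        residue_indices[i] = resmap[key]
        residue_names[i] = a.resname

    # molecule assignment: explicit map > chainID > segment > one molecule
    molecule_ids = np.zeros(n, dtype=int)
    if molecule_map is not None:
        # molecule_map: list of (first_residue, last_residue) 0-based ranges
        for mol_id, (lo, hi) in enumerate(molecule_map):
            molecule_ids[(residue_indices >= lo) & (residue_indices <= hi)] = mol_id
    else:
        try:
            chains = np.array([getattr(a, "chainID", "") for a in u.atoms],
                              dtype=object)
        except Exception:
            chains = np.array([""] * n, dtype=object)
        if len(set(chains)) > 1:
            uniq = {c: i for i, c in enumerate(dict.fromkeys(chains))}
            molecule_ids = np.array([uniq[c] for c in chains])
        else:
            segids = np.array([a.segid for a in u.atoms], dtype=object)
            uniq = {s: i for i, s in enumerate(dict.fromkeys(segids))}
            molecule_ids = np.array([uniq[s] for s in segids])

    molecules = [
        Molecule(int(m),
                 int(residue_indices[molecule_ids == m].min()),
                 int(residue_indices[molecule_ids == m].max()))
        for m in np.unique(molecule_ids)
    ]
    return Topology(names, elements, masses, residue_indices, residue_names,
                    molecule_ids, molecules)


def read_structure(path, fmt: str | None = None, molecule_map=None
                   ) -> tuple[Topology, Trajectory]:
    """Read a PDB or GRO structure into (Topology, single/multi-frame Trajectory).

    Coordinates are converted to nm.  Multi-chain PDB files yield one
    molecule per chain unless ``molecule_map`` (a list of 0-based residue
    ranges) overrides the assignment.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        u = mda.Universe(str(path), format=fmt)
    except Exception as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc
    top = _topology_from_universe(u, molecule_map)

    frames, boxes, times = [], [], []
    for ts in u.trajectory:
        frames.append(u.atoms.positions * _A_TO_NM)
        boxes.append(_check_orthorhombic(ts.dimensions))
        times.append(ts.time if ts.time else len(times) * 1.0)
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = np.arange(len(frames), dtype=float)
    traj = Trajectory(top, np.array(frames), times, np.array(boxes))
    return top, traj


def read_trajectory(path, topology: Topology, fmt: str | None = None,
                    structure_path=None, dt: float | None = None) -> Trajectory:
    """Read a trajectory (XTC or multi-model PDB) against a known topology.

    ``dt`` (ps) overrides file times when the format carries none.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if structure_path is not None:
        u = mda.Universe(str(structure_path), str(path), format=fmt)
    else:
        u = mda.Universe(str(path), format=fmt)
    if len(u.atoms) != topology.n_atoms:
        raise ValueError(
            f"trajectory atom count {len(u.atoms)} != topology "
            f"{topology.n_atoms}")
    frames, boxes, times = [], [], []
    for ts in u.trajectory:
        frames.append(u.atoms.positions * _A_TO_NM)
        boxes.append(_check_orthorhombic(ts.dimensions))
        times.append(ts.time)
    times = np.asarray(times, dtype=float)
    if dt is not None or np.any(np.diff(times) <= 0) or np.all(times == 0):
        times = np.arange(len(frames), dtype=float) * (dt or 1.0)
    return Trajectory(topology, np.array(frames), times, np.array(boxes))


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    """Write a Trajectory to PDB (multi-model), GRO (first frame) or XTC."""
    import MDAnalysis as mda

    path = Path(path)
    u = _universe_from(traj)
    suffix = (fmt or path.suffix.lstrip(".")).upper()
    n_frames = traj.n_frames if suffix != "GRO" else 1
    with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
        for f in range(n_frames):
            u.atoms.positions = traj.xyz[f] * _NM_TO_A
            u.trajectory.ts.dimensions = np.concatenate(
                [traj.boxes[f] * _NM_TO_A, [90.0, 90.0, 90.0]])
            u.trajectory.ts.time = traj.times[f]
            u.trajectory.ts.frame = f
            w.write(u.atoms)


def _universe_from(traj: Trajectory):
    import MDAnalysis as mda

    top = traj.topology
    resid_of_atom = top.residue_indices
    uniq_res, res_first = np.unique(resid_of_atom, return_index=True)
    n_res = len(uniq_res)
    res_per_atom = np.searchsorted(uniq_res, resid_of_atom)
    res_mol = top.molecule_ids[res_first]
    uniq_mol = np.unique(res_mol)
    seg_per_res = np.searchsorted(uniq_mol, res_mol)
    u = mda.Universe.empty(top.n_atoms, n_residues=n_res,
                           n_segments=len(uniq_mol),
                           atom_resindex=res_per_atom,
                           residue_segindex=seg_per_res,
                           trajectory=True)
    u.add_TopologyAttr("names", [str(x) for x in top.names])
    u.add_TopologyAttr("elements", [str(x) for x in top.elements])
    u.add_TopologyAttr("masses", top.masses)
    u.add_TopologyAttr("resnames",
                       [str(top.residue_names[i]) for i in res_first])
    u.add_TopologyAttr("resids", (uniq_res + 1).tolist())
    segids = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    u.add_TopologyAttr("segids", [segids[i % 26] for i in range(len(uniq_mol))])
    u.add_TopologyAttr(
        "chainIDs",
        [segids[seg_per_res[res_per_atom[i]] % 26] for i in range(top.n_atoms)])
    u.atoms.positions = traj.xyz[0] * _NM_TO_A
    u.trajectory.ts.dimensions = np.concatenate(
        [traj.boxes[0] * _NM_TO_A, [90.0, 90.0, 90.0]])
    return u
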