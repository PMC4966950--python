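"""Per-frame and per-trajectory structural descriptors.

Superposition and RMSD (Kabsch), radius of gyration, RMSF about the
iterated mean structure, a dihedral/run-length helix assignment, and 2-D
sampling maps such as (RMSD, Rg) occupancy histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Selection, Trajectory


# ---------------------------------------------------------------------------
# superposition / RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD.  The
    rotation is always proper (det = +1); reflections are excluded, which is
    what makes the minimum physical for chiral molecules.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2:
        raise ValueError("point sets must share shape (n, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    w = (np.ones(n) if weights is None else np.asarray(weights, float))
    w = w / w.sum()
    mu_m = w @ mobile
    mu_r = w @ reference
    a = mobile - mu_m
    b = reference - mu_r
    # collinearity guard: a rank-<2 reference leaves the rotation unpinned
    if np.linalg.matrix_rank(b - b.mean(0), tol=1e-10) < 2:
        raise ValueError("reference points are collinear or degenerate")
    h = (a * w[:, None]).T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = mu_r - rot @ mu_m
    moved = a @ rot.T
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - b) ** 2, axis=1))))
    return rot, trans, rmsd


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                selection: Selection | None = None,
                weights: np.ndarray | None = None) -> np.ndarray:
    """Per-frame RMSD (nm) to a reference, each frame superposed
    independently before the deviation is measured."""
    idx = (selection.indices if selection is not None
           else np.arange(traj.n_atoms))
    ref = np.asarray(reference, float)
    if ref.shape[0] == traj.n_atoms and len(idx) != traj.n_atoms:
        ref = ref[idx]
    return np.array([kabsch_superpose(traj.xyz[f, idx], ref, weights)[2]
                     for f in range(traj.n_frames)])


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray | None = None,
                       mass_weighted: bool = True) -> float:
    """Radius of gyration (nm): sqrt(sum m_i |r_i - r_com|^2 / sum m_i)."""
    frame = np.asarray(frame, float)
    if frame.ndim != 2 or len(frame) < 1:
        raise ValueError("frame must be a non-empty (n, 3) array")
    if masses is None or not mass_weighted:
        m = np.ones(len(frame))
    else:
        m = np.asarray(masses, float)
    com = m @ frame / m.sum()
    return float(np.sqrt(np.sum(m * np.sum((frame - com) ** 2, 1)) / m.sum()))


def rg_series(traj: Trajectory, selection: Selection | None = None,
              mass_weighted: bool = True) -> np.ndarray:
    idx = (selection.indices if selection is not None
           else np.arange(traj.n_atoms))
    m = traj.topology.masses[idx]
    return np.array([radius_of_gyration(traj.xyz[f, idx], m, mass_weighted)
                     for f in range(traj.n_frames)])


def superpose_onto_mean(coords: np.ndarray, weights: np.ndarray | None = None,
                        max_iter: int = 20, tol: float = 1e-8) -> np.ndarray:
    """Iteratively superpose every frame onto the ensemble mean structure
    until the mean stops moving.  Removes global rigid motion."""
    coords = np.asarray(coords, float)
    out = coords.copy()
    mean = out[0]
    for _ in range(max_iter):
        for f in range(len(out)):
            rot, trans, _ = kabsch_superpose(out[f], mean, weights)
            out[f] = out[f] @ rot.T + trans
        new_mean = out.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            break
        mean = new_mean
    return out


def rmsf(traj: Trajectory, selection: Selection | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (nm) about the iterated mean
    structure, after removing rigid-body motion by superposition."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = (selection.indices if selection is not None
           else np.arange(traj.n_atoms))
    sup = superpose_onto_mean(traj.xyz[:, idx, :])
    mean = sup.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sup - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# secondary structure (helicity)
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.degrees(np.arctan2(m1 @ n2, n1 @ n2)))


def _runs_to_labels(helical: np.ndarray, min_run: int = 4) -> np.ndarray:
    """Keep only qualifying residues inside runs of >= min_run."""
    labels = np.full(len(helical), "C", dtype=object)
    i = 0
    while i < len(helical):
        if helical[i]:
            j = i
            while j < len(helical) and helical[j]:
                j += 1
            if j - i >= min_run:
                labels[i:j] = "H"
            i = j
        else:
            i += 1
    return labels


def assign_secondary_structure(traj: Trajectory,
                               selection: Selection | None = None
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Helix/coil assignment per residue per frame.

    With full backbone (N, CA, C) present the rule is dihedral-based: a
    residue qualifies when phi in [-100, -30] and psi in [-80, -5] degrees,
    and is labeled H only inside a run of at least 4 qualifying residues.
    With Calpha-only input the fallback rule marks residues whose i -> i+3
    Calpha distance lies in the ideal-helix band [0.49, 0.56] nm, same run
    rule.  Returns ``(labels (n_frames, n_res), helicity % per residue)``.
    """
    sub = traj if selection is None else traj.slice_atoms(selection)
    top = sub.topology
    res_ids = np.unique(top.residue_indices)
    names = top.names
    has_backbone = all(
        any((top.residue_indices == r) & (names == nm))
        for r in res_ids for nm in ("N", "CA", "C"))
    if not has_backbone and not all(
            any((top.residue_indices == r) & (names == "CA"))
            for r in res_ids):
        raise ValueError("need backbone or at least Calpha atoms per residue")
    if not has_backbone:
        warnings.warn("backbone incomplete; using Calpha-only helix rule")

    labels = np.empty((sub.n_frames, len(res_ids)), dtype=object)
    for f in range(sub.n_frames):
        frame = sub.xyz[f]
        if has_backbone:
            qual = _phi_psi_qualify(top, frame, res_ids)
        else:
            qual = _ca_qualify(top, frame, res_ids)
        labels[f] = _runs_to_labels(qual)
    helicity = 100.0 * np.mean(labels == "H", axis=0)
    return labels, helicity


def _phi_psi_qualify(top, frame, res_ids) -> np.ndarray:
    def atom(r, nm):
        hit = np.flatnonzero((top.residue_indices == r) & (top.names == nm))
        return frame[hit[0]] if len(hit) else None

    qual = np.zeros(len(res_ids), dtype=bool)
    for k, r in enumerate(res_ids):
        if k == 0 or k == len(res_ids) - 1:
            continue
        prev_c = atom(res_ids[k - 1], "C")
        n, ca, c = atom(r, "N"), atom(r, "CA"), atom(r, "C")
        next_n = atom(res_ids[k + 1], "N")
        if any(p is None for p in (prev_c, n, ca, c, next_n)):
            continue
        phi = _dihedral(prev_c, n, ca, c)
        psi = _dihedral(n, ca, c, next_n)
        qual[k] = (-100.0 <= phi <= -30.0) and (-80.0 <= psi <= -5.0)
    return qual


def _ca_qualify(top, frame, res_ids) -> np.ndarray:
    ca = np.array([frame[np.flatnonzero(
        (top.residue_indices == r) & (top.names == "CA"))[0]]
        for r in res_ids])
    qual = np.zeros(len(res_ids), dtype=bool)
    if len(ca) >= 4:
        d = np.linalg.norm(ca[3:] - ca[:-3], axis=1)
        # residue i qualifies when its own i -> i+3 segment is helix-like;
        # the run rule then demands 4 consecutive such segments
        qual[:len(d)] = (d >= 0.49) & (d <= 0.56)
    return qual


# ---------------------------------------------------------------------------
# sampling maps
# ---------------------------------------------------------------------------

@dataclass
class SamplingMap:
    """2-D occupancy histogram over a pair of descriptors."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    x_label: str = "x"
    y_label: str = "y"
    normalized: bool = False

    def to_dataframe(self):
        import pandas as pd
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame({self.x_label: xx.ravel(),
                             self.y_label: yy.ravel(),
                             "count": self.counts.ravel()})


def sampling_map(x_series, y_series, bins=40, x_label="x", y_label="y",
                 normalize: bool = False) -> SamplingMap:
    """2-D histogram of two per-frame descriptor series (e.g. RMSD vs Rg)."""
    x = np.asarray(x_series, float)
    y = np.asarray(y_series, float)
    if len(x) == 0 or len(x) != len(y):
        raise ValueError("series must be non-empty and equal length")
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    if normalize:
        counts = counts / counts.sum()
    return SamplingMap(xe, ye, counts, x_label, y_label, normalize)
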