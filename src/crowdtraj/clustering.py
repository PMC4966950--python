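"""GROMOS conformational clustering and conformational-change timing.

The GROMOS algorithm is a greedy neighbor-count scheme on the pairwise
(optimal-superposition) RMSD matrix: the structure with most neighbors
within the cutoff becomes a cluster center, it and its neighbors are
removed, and the step repeats until every structure is assigned.  The
two-step protocol first reduces each trajectory at a tight cutoff
(0.15 nm) and then pools the per-trajectory centers, weighted by their
populations, into a joint clustering at a looser cutoff (0.35 nm), which
makes conformer sets comparable across environments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Selection, Trajectory
from .descriptors import kabsch_superpose

CUTOFF_STEP1 = 0.15   # nm
CUTOFF_STEP2 = 0.35   # nm
CUTOFF_CHANGE = 0.15  # nm (0.10 for notably rigid folds)


@dataclass
class ClusterAssignment:
    """Per-frame labels, cluster centers and populations."""

    labels: np.ndarray            # per-frame cluster id, 0..k-1
    centers: np.ndarray           # frame index of each cluster's center
    populations: np.ndarray       # fraction of total weight per cluster
    cutoff: float
    metric: str = "pairwise-superposed-RMSD"
    environment_occupancy: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.labels < 0):
            raise ValueError("all frames must be assigned")
        if abs(self.populations.sum() - 1.0) > 1e-9:
            raise ValueError("populations must sum to 1")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def _batch_rmsd(a_centered: np.ndarray, b_centered: np.ndarray,
                ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Optimally superposed RMSD for aligned stacks of centered frames.

    Uses the Kabsch identity rmsd^2 = (Ga + Gb - 2 D)/m where D is the sum
    of singular values of the cross-covariance, the smallest negated when
    the optimal transform would be a reflection.
    """
    m = a_centered.shape[1]
    h = np.einsum("pmi,pmj->pij", a_centered, b_centered)
    comps = tuple(h[:, x, y] for x in range(3) for y in range(3))
    d = _qcp_max_overlap(comps, 0.5 * (ga + gb))
    e = np.maximum(ga + gb - 2.0 * d, 0.0)
    return np.sqrt(e / m)


def _qcp_max_overlap(comps, lam0: np.ndarray) -> np.ndarray:
    """Largest eigenvalue of the quaternion key matrix (Theobald's QCP).

    Equals the maximal rotational overlap tr(R H) over proper rotations —
    the reflection-free equivalent of the sum of signed singular values.
    Solved by Newton iteration on the quartic characteristic polynomial
    lam^4 + c2 lam^2 + c1 lam + c0, started from the upper bound
    (Ga + Gb)/2; fully vectorized over pairs.  ``comps`` holds the nine
    cross-covariance components (sxx, sxy, ..., szz) as same-shape arrays.
    """
    sxx, sxy, sxz, syx, syy, syz, szx, szy, szz = comps

    c2 = -2.0 * (sxx**2 + sxy**2 + sxz**2 + syx**2 + syy**2 + syz**2
                 + szx**2 + szy**2 + szz**2)
    c1 = 8.0 * (sxx * syz * szy + syy * szx * sxz + szz * sxy * syx
                - sxx * syy * szz - syz * szx * sxy - szy * syx * sxz)

    sxzpszx = sxz + szx
    syzpszy = syz + szy
    sxypsyx = sxy + syx
    syzmszy = syz - szy
    sxzmszx = sxz - szx
    sxymsyx = sxy - syx
    sxxpsyy = sxx + syy
    sxxmsyy = sxx - syy
    sxy2sxz2syx2szx2 = sxy**2 + sxz**2 - syx**2 - szx**2
    sxx2syy2szz2syz2szy2 = syy**2 + szz**2 - sxx**2 + syz**2 + szy**2
    syzszymsyyszz2 = 2.0 * (syz * szy - syy * szz)

    c0 = (sxy2sxz2syx2szx2 * sxy2sxz2syx2szx2
          + (sxx2syy2szz2syz2szy2 + syzszymsyyszz2)
          * (sxx2syy2szz2syz2szy2 - syzszymsyyszz2)
          + (-sxzpszx * syzmszy + sxymsyx * (sxxmsyy - szz))
          * (-sxzmszx * syzpszy + sxymsyx * (sxxmsyy + szz))
          + (-sxzpszx * syzpszy - sxypsyx * (sxxpsyy - szz))
          * (-sxzmszx * syzmszy - sxypsyx * (sxxpsyy + szz))
          + (sxypsyx * syzpszy + sxzpszx * (sxxmsyy + szz))
          * (-sxymsyx * syzmszy + sxzpszx * (sxxpsyy + szz))
          + (sxypsyx * syzmszy + sxzmszx * (sxxmsyy - szz))
          * (-sxymsyx * syzpszy + sxzmszx * (sxxpsyy - szz)))

    # Newton from the upper bound is monotone; the error at least halves
    # per step (double-root worst case), so 24 iterations bound the
    # relative error on the ensuing squared deviation by ~2^-24.
    lam = lam0.copy()
    lam2 = np.empty_like(lam)
    p = np.empty_like(lam)
    dp = np.empty_like(lam)
    tmp = np.empty_like(lam)
    two_c2 = 2.0 * c2
    tiny = np.asarray(1e-30, dtype=lam.dtype)
    for _ in range(24):
        np.multiply(lam, lam, out=lam2)
        # p = (lam2 + c2)*lam2 + c1*lam + c0
        np.add(lam2, c2, out=p)
        np.multiply(p, lam2, out=p)
        np.multiply(c1, lam, out=tmp)
        p += tmp
        p += c0
        # dp = (4*lam2 + 2*c2)*lam + c1
        np.multiply(lam2, 4.0, out=dp)
        dp += two_c2
        np.multiply(dp, lam, out=dp)
        dp += c1
        # a vanishing derivative means lam already sits on a repeated root
        np.abs(dp, out=tmp)
        np.maximum(tmp, tiny, out=tmp)
        np.copysign(tmp, dp, out=dp)
        np.divide(p, dp, out=p)
        lam -= p
    return lam


def pairwise_rmsd(coords: np.ndarray, block: int = 250_000) -> np.ndarray:
    """Symmetric matrix of per-pair optimally superposed RMSD (nm).

    Computed in blocks of pairs; the result is independent of block size.
    """
    coords = np.asarray(coords, float)
    n = len(coords)
    centered = coords - coords.mean(axis=1, keepdims=True)
    g = np.einsum("pmi,pmi->p", centered, centered)
    out = np.zeros((n, n))
    ii, jj = np.triu_indices(n, k=1)
    for s in range(0, len(ii), block):
        i, j = ii[s:s + block], jj[s:s + block]
        r = _batch_rmsd(centered[i], centered[j], g[i], g[j])
        out[i, j] = r
        out[j, i] = r
    return out


def _adjacency(coords: np.ndarray, cutoff: float,
               row_block: int = 500) -> np.ndarray:
    """Boolean matrix of frame pairs within the RMSD cutoff.

    Computed in row blocks: the nine cross-covariance components of every
    (block-frame, frame) pair come from dense matrix products, and the QCP
    overlap turns them into squared deviations without per-pair
    factorizations.  The result is independent of the block size.
    """
    coords = np.asarray(coords, float)
    n, m, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    g = np.einsum("pmi,pmi->p", centered, centered)
    comp = [np.ascontiguousarray(centered[:, :, x]) for x in range(3)]
    e_cut = cutoff * cutoff * m
    adj = np.zeros((n, n), dtype=bool)
    for s in range(0, n, row_block):
        t = min(s + row_block, n)
        cols = slice(s, n)  # upper triangle only; mirrored below
        comps = tuple(comp[x][s:t] @ comp[y][cols].T
                      for x in range(3) for y in range(3))
        gsum = g[s:t, None] + g[None, cols]
        lam = _qcp_max_overlap(comps, 0.5 * gsum)
        adj[s:t, cols] = gsum - 2.0 * lam <= e_cut
    np.fill_diagonal(adj, True)
    return adj | adj.T


def gromos_cluster(coords_or_traj, cutoff: float,
                   selection: Selection | None = None,
                   weights: np.ndarray | None = None) -> ClusterAssignment:
    """GROMOS clustering of trajectory frames (or a raw (n, m, 3) stack).

    Each pair of frames is optimally superposed before its RMSD is taken.
    """
    if isinstance(coords_or_traj, Trajectory):
        traj = coords_or_traj
        idx = (selection.indices if selection is not None
               else np.arange(traj.n_atoms))
        coords = traj.xyz[:, idx, :]
    else:
        coords = np.asarray(coords_or_traj, float)
    if len(coords) == 0:
        raise ValueError("cannot cluster an empty trajectory")
    adj = _adjacency(coords, cutoff)
    labels, centers = _cluster_with_centers(adj, cutoff, weights)
    w = np.ones(len(coords)) if weights is None else np.asarray(weights, float)
    pops = np.array([w[labels == k].sum() for k in range(labels.max() + 1)])
    pops = pops / w.sum()
    return ClusterAssignment(labels, centers, pops, cutoff)


def _cluster_with_centers(adj: np.ndarray, cutoff: float,
                          weights: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Greedy neighbor-count clustering on a boolean adjacency matrix.

    Ties on the (weighted) neighbor count break to the lowest frame index,
    which makes the partition deterministic.
    """
    n = len(adj)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    labels = np.full(n, -1, dtype=int)
    remaining = np.ones(n, dtype=bool)
    centers = []
    while remaining.any():
        counts = np.where(remaining, (adj & remaining[None, :]) @ w, -np.inf)
        center = int(np.argmax(counts))
        members = np.flatnonzero(adj[center] & remaining)
        labels[members] = len(centers)
        remaining[members] = False
        centers.append(center)
    return labels, np.array(centers)


def two_step_cluster(trajectories: dict, cutoff1: float = CUTOFF_STEP1,
                     cutoff2: float = CUTOFF_STEP2,
                     selection: Selection | None = None
                     ) -> tuple[ClusterAssignment, dict]:
    """Two-step protocol across environments.

    ``trajectories`` maps environment label -> Trajectory of the same
    protein (same selection size).  Step 1 clusters each trajectory at
    ``cutoff1``; step 2 pools the step-1 centers, weighted by their cluster
    populations, into a joint clustering at ``cutoff2``.  The returned
    assignment carries per-environment occupancancies of every joint
    cluster; the second return value holds the step-1 assignments.
    """
    env_labels = list(trajectories)
    pooled_coords, pooled_w, pooled_env = [], [], []
    step1 = {}
    n_sel = None
    for env in env_labels:
        traj = trajectories[env]
        idx = (selection.indices if selection is not None
               else np.arange(traj.n_atoms))
        if n_sel is None:
            n_sel = len(idx)
        elif len(idx) != n_sel or traj.xyz.shape[1] < idx.max() + 1:
            raise ValueError("selections mismatch across environments")
        a = gromos_cluster(traj, cutoff1, selection)
        step1[env] = a
        for k, center in enumerate(a.centers):
            pooled_coords.append(traj.xyz[center, idx, :])
            pooled_w.append(a.populations[k])
            pooled_env.append(env)
    pooled_coords = np.array(pooled_coords)
    pooled_w = np.array(pooled_w)
    joint = gromos_cluster(pooled_coords, cutoff2, weights=pooled_w)
    # per-environment occupancy of each joint cluster
    occ = {}
    for env in env_labels:
        mask = np.array([e == env for e in pooled_env])
        env_total = pooled_w[mask].sum()
        occ[env] = np.array([
            pooled_w[mask & (joint.labels == k)].sum() / env_total
            for k in range(joint.n_clusters)])
    joint.environment_occupancy = occ
    return joint, step1


def environment_overlap(joint: ClusterAssignment) -> dict:
    """Pairwise conformational overlap between environments.

    overlap(a, b) = sum_k min(occ_a(k), occ_b(k)) in [0, 1]; 1 for
    identical occupancy vectors, 0 for disjoint cluster usage.  Also
    reports the shared-cluster count as an alternative reading.
    """
    occ = joint.environment_occupancy
    envs = list(occ)
    if len(envs) < 2:
        raise ValueError("need at least 2 environments for overlap")
    out = {}
    for i, a in enumerate(envs):
        for b in envs[i + 1:]:
            out[(a, b)] = {
                "overlap": float(np.minimum(occ[a], occ[b]).sum()),
                "shared_clusters": int(np.sum((occ[a] > 0) & (occ[b] > 0))),
            }
    return out


def conformational_change_times(traj: Trajectory,
                                cutoff: float = CUTOFF_CHANGE,
                                selection: Selection | None = None,
                                assignment: ClusterAssignment | None = None
                                ) -> dict:
    """Number of large conformational changes and the mean time between
    them.

    Frames are clustered (GROMOS, all-atom by default) and every change of
    cluster label between consecutive frames counts as one conformational
    change; mean time = total simulated span / number of changes.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to detect changes")
    a = assignment or gromos_cluster(traj, cutoff, selection)
    changes = int(np.sum(a.labels[1:] != a.labels[:-1]))
    span = float(traj.times[-1] - traj.times[0])
    return {
        "n_transitions": changes,
        "mean_time_ps": span / changes if changes else None,
        "no_transitions": changes == 0,
        "n_clusters": a.n_clusters,
        "cutoff_nm": cutoff,
    }
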