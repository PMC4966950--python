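"""Independent brute-force oracles used by the test suite.

These are deliberately naive reimplementations — loops, exhaustive grids —
kept free of any code path from the package under test.
"""

import numpy as np
from scipy.spatial.transform import Rotation


def reference_rmsd(a, b):
    """Superposed RMSD via scipy's rotation fitting (proper rotations)."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(b0, a0)
    return rssd / np.sqrt(len(a))


def reference_gromos(frames, cutoff):
    """Greedy neighbor-count clustering, coded with plain loops.

    Tie-break: lowest frame index wins.  Returns per-frame labels.
    """
    n = len(frames)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = reference_rmsd(frames[i], frames[j])
    labels = [-1] * n
    k = 0
    remaining = set(range(n))
    while remaining:
        best, best_count = None, -1
        for c in sorted(remaining):
            count = sum(1 for o in remaining if dist[c, o] <= cutoff)
            if count > best_count:
                best, best_count = c, count
        for m in [o for o in sorted(remaining) if dist[best, o] <= cutoff]:
            labels[m] = k
            remaining.discard(m)
        k += 1
    return np.array(labels)


def grid_min_rmsd(a, b):
    """Minimum RMSD over rigid transforms by coarse-to-fine search on a
    z-y-z Euler-angle grid (translation handled by centering both clouds).
    """
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def eval_angles(alpha, beta, gamma):
        grid = np.array(np.meshgrid(alpha, beta, gamma,
                                    indexing="ij")).reshape(3, -1).T
        mats = Rotation.from_euler("zyz", grid, degrees=True).as_matrix()
        moved = np.einsum("rij,nj->rni", mats, a0)
        d = moved - b0
        rmsds = np.sqrt(np.mean(np.sum(d * d, axis=-1), axis=1))
        best = int(np.argmin(rmsds))
        return grid[best], float(rmsds[best])

    best_ang, best = eval_angles(np.arange(-180.0, 180.0, 10.0),
                                 np.arange(0.0, 180.1, 10.0),
                                 np.arange(-180.0, 180.0, 10.0))
    step = 10.0
    for _ in range(3):
        step /= 5.0
        spans = [np.arange(c - 5 * step, c + 5 * step + 1e-9, step)
                 for c in best_ang]
        best_ang, best = eval_angles(*spans)
    return best
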