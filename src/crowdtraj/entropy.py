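"""Quasi-harmonic conformational entropy.

Fluctuations about the mean structure are treated as a set of independent
harmonic modes obtained from the mass-weighted covariance matrix

    C = < M^(1/2) dx dx^T M^(1/2) >,   dx = x - <x>

whose eigenvalues lambda_i (amu nm^2) define mode frequencies
omega_i = sqrt(kB T / lambda_i).  Each mode contributes the quantum
harmonic-oscillator entropy

    S_i / kB = a_i / (exp(a_i) - 1) - ln(1 - exp(-a_i)),
    a_i = hbar omega_i / (kB T)

so stiff modes (small lambda) contribute nothing and soft modes dominate.
Rigid-body translation/rotation is removed by superposing all frames onto
the mean before the covariance is accumulated, and the six near-zero
eigenvalues that remain are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Selection, Trajectory
from .descriptors import superpose_onto_mean
from .constants import (KB_J_PER_K, HBAR_J_S, AMU_KG, NM_M,
                        GAS_CONSTANT_J_PER_MOL_K)

RIGID_BODY_EIGENVALUE_FLOOR = 1e-8  # amu nm^2


@dataclass
class EntropyResult:
    """Quasi-harmonic entropy with the spectrum it came from."""

    s_j_per_mol_k: float
    s_kb: float                       # in units of kB per molecule
    eigenvalues: np.ndarray           # amu nm^2, after filtering
    n_frames: int
    temperature: float
    selection_label: str = ""
    window: tuple = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.s_j_per_mol_k < -1e-12:
            raise ValueError("entropy must be non-negative")


def mass_weighted_covariance(traj: Trajectory,
                             selection: Selection | None = None,
                             window: tuple = (0.0, 1.0),
                             superpose: bool = True
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Mass-weighted covariance of positional fluctuations and its
    eigenvalue spectrum (amu nm^2, ascending).

    ``window`` selects a fraction of the trajectory (default all; the
    trailing portion, e.g. (0.5, 1.0), mimics analyzing only the
    equilibrated tail).  ``superpose`` removes rigid-body motion first;
    disable it only for fixtures generated without rigid-body noise.
    """
    idx = (selection.indices if selection is not None
           else np.arange(traj.n_atoms))
    lo = int(window[0] * traj.n_frames)
    hi = int(window[1] * traj.n_frames)
    coords = traj.xyz[lo:hi, idx, :]
    if len(coords) < 2:
        raise ValueError("covariance needs at least 2 frames")
    if superpose:
        coords = superpose_onto_mean(coords, traj.topology.masses[idx])
    n_atoms = coords.shape[1]
    if len(coords) < 3 * n_atoms:
        import warnings
        warnings.warn(
            f"{len(coords)} frames < 3N = {3 * n_atoms}: covariance is "
            "rank-deficient; trailing eigenvalues are truncation artifacts")
    flat = coords.reshape(len(coords), 3 * n_atoms)
    dx = flat - flat.mean(axis=0)
    sqrt_m = np.sqrt(np.repeat(traj.topology.masses[idx], 3))
    y = dx * sqrt_m
    cov = y.T @ y / len(y)
    evals = np.linalg.eigvalsh(cov)
    return cov, evals


def quasiharmonic_entropy(eigenvalues: np.ndarray, temperature: float,
                          n_frames: int = 0, selection_label: str = "",
                          drop_rigid_body: bool = True,
                          window: tuple = (0.0, 1.0)) -> EntropyResult:
    """Entropy from a mass-weighted covariance spectrum (amu nm^2).

    With ``drop_rigid_body`` the six smallest eigenvalues are discarded
    (superposition leaves six near-zero rigid-body modes), along with any
    eigenvalue below 1e-8 amu nm^2 whose frequency would diverge.
    """
    ev = np.sort(np.asarray(eigenvalues, float))
    if drop_rigid_body and len(ev) > 6:
        ev = ev[6:]
    ev = ev[ev > RIGID_BODY_EIGENVALUE_FLOOR]
    if len(ev) == 0:
        return EntropyResult(0.0, 0.0, ev, n_frames, temperature,
                             selection_label, window)
    if np.any(ev <= 0):
        raise ValueError("non-positive eigenvalue after filtering")
    ev_si = ev * AMU_KG * NM_M ** 2           # kg m^2
    kt = KB_J_PER_K * temperature
    omega = np.sqrt(kt / ev_si)               # 1/s
    a = HBAR_J_S * omega / kt
    per_mode = a / np.expm1(a) - np.log1p(-np.exp(-a))
    s_kb = float(per_mode.sum())
    return EntropyResult(s_kb * GAS_CONSTANT_J_PER_MOL_K, s_kb, ev,
                         n_frames, temperature, selection_label, window)


def backbone_entropy(traj: Trajectory, temperature: float = 300.0,
                     window: tuple = (0.0, 1.0),
                     backbone_names=("N", "CA", "C", "O"),
                     superpose: bool = True) -> EntropyResult:
    """Quasi-harmonic entropy of the backbone (N, CA, C, O) atoms."""
    sel = traj.topology.select(names=backbone_names, label="backbone")
    if len(sel) == 0:
        sel = traj.topology.calpha()
        sel.label = "CA-only"
    _, evals = mass_weighted_covariance(traj, sel, window, superpose)
    res = quasiharmonic_entropy(evals, temperature,
                                n_frames=traj.n_frames,
                                selection_label=sel.label, window=window,
                                drop_rigid_body=superpose)
    return res


def entropy_difference(result_env: EntropyResult,
                       result_ref: EntropyResult,
                       traj_env: Trajectory | None = None,
                       traj_ref: Trajectory | None = None,
                       n_boot: int = 50, block: int = 20,
                       temperature: float | None = None,
                       seed: int = 0) -> dict:
    """Entropy difference (environment minus reference) with an optional
    block-bootstrap uncertainty.

    When the trajectories are supplied, frames are resampled in contiguous
    blocks of ``block`` frames and the covariance/entropy recomputed
    ``n_boot`` times per side; the reported uncertainty is the standard
    deviation of the bootstrap differences.
    """
    if result_env.selection_label != result_ref.selection_label:
        raise ValueError("entropy difference requires matching selections")
    if result_env.temperature != result_ref.temperature:
        raise ValueError("entropy difference requires equal temperatures")
    delta = result_env.s_j_per_mol_k - result_ref.s_j_per_mol_k
    out = {"delta_s_j_per_mol_k": float(delta),
           "delta_s_kb": float(result_env.s_kb - result_ref.s_kb),
           "uncertainty_j_per_mol_k": None}
    if traj_env is not None and traj_ref is not None:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            s = []
            for traj, res in ((traj_env, result_env), (traj_ref, result_ref)):
                bt = _block_resample(traj, block, rng)
                r = backbone_entropy(bt, res.temperature, window=(0.0, 1.0))
                s.append(r.s_j_per_mol_k)
            boots.append(s[0] - s[1])
        out["uncertainty_j_per_mol_k"] = float(np.std(boots, ddof=1))
    return out


def _block_resample(traj: Trajectory, block: int, rng) -> Trajectory:
    n = traj.n_frames
    n_blocks = max(1, n // block)
    starts = rng.integers(0, max(1, n - block), size=n_blocks)
    frames = np.concatenate([traj.xyz[s:s + block] for s in starts])
    times = np.arange(len(frames), dtype=float)
    boxes = np.tile(traj.boxes[0], (len(frames), 1))
    return Trajectory(traj.topology, frames, times, boxes)
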