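"""Helix-axis vectors and relative (elevation, azimuth) orientation.

A helix axis is the first principal axis of its Calpha positions, with the
sign fixed to point from the N- toward the C-terminal end.  The relative
orientation of a second helix is reported in a molecular frame built from
an axis vector (z) and an in-plane reference vector (x = the component of
the reference perpendicular to z; y = z cross x):

    elevation = 90 deg - angle(target, z), signed into [-90, 90]
    azimuth   = atan2(target . y, target . x) in (-180, 180]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory
from .descriptors import SamplingMap


@dataclass
class HelixDefinition:
    """A helix as a residue range frozen from the reference structure."""

    label: str
    first_residue: int   # 0-based, inclusive
    last_residue: int    # inclusive

    def __post_init__(self) -> None:
        if self.last_residue - self.first_residue + 1 < 4:
            raise ValueError("a helix definition needs >= 4 residues")


def helix_vector(frame: np.ndarray, topology, helix: HelixDefinition
                 ) -> np.ndarray:
    """Unit axis of the helix's Calpha subset in one frame.

    First principal axis of the positional covariance; sign chosen so the
    projection of (last Calpha - first Calpha) on the axis is positive.
    """
    rows = np.flatnonzero(
        (topology.residue_indices >= helix.first_residue)
        & (topology.residue_indices <= helix.last_residue)
        & (topology.names == "CA"))
    if len(rows) < 4:
        raise ValueError(f"helix {helix.label}: fewer than 4 Calpha atoms")
    ca = frame[rows]
    centered = ca - ca.mean(axis=0)
    cov = centered.T @ centered / len(ca)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 1e-12 or np.isclose(evals[-1], evals[0], atol=1e-12):
        raise ValueError(f"helix {helix.label}: degenerate (spherical) "
                         "Calpha set has no principal axis")
    axis = evecs[:, -1]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def elevation_azimuth(v_axis: np.ndarray, v_plane: np.ndarray,
                      v_target: np.ndarray, pole_tol: float = 1e-9
                      ) -> tuple[float, float, bool]:
    """(elevation deg, azimuth deg, degenerate flag) of a target vector in
    the frame defined by z = v_axis and x = v_plane's component ⊥ z.

    At the pole (target parallel to the axis) the azimuth is undefined and
    reported as 0 with the degenerate flag set.
    """
    z = np.asarray(v_axis, float)
    z = z / np.linalg.norm(z)
    p = np.asarray(v_plane, float)
    x = p - (p @ z) * z
    nx = np.linalg.norm(x)
    if nx < 1e-9:
        raise ValueError("frame vectors are parallel; molecular frame "
                         "undefined")
    x = x / nx
    y = np.cross(z, x)
    t = np.asarray(v_target, float)
    t = t / np.linalg.norm(t)
    elevation = 90.0 - np.degrees(np.arccos(np.clip(t @ z, -1.0, 1.0)))
    tx, ty = t @ x, t @ y
    if abs(tx) < pole_tol and abs(ty) < pole_tol:
        return float(elevation), 0.0, True
    azimuth = np.degrees(np.arctan2(ty, tx))
    if azimuth <= -180.0:
        azimuth += 360.0
    return float(elevation), float(azimuth), False


def orientation_series(traj: Trajectory, axis_helix: HelixDefinition,
                       target_helix: HelixDefinition,
                       plane_reference=(1.0, 0.0, 0.0)) -> np.ndarray:
    """(n_frames, 2) elevation/azimuth of the target helix relative to the
    axis helix, using ``plane_reference`` to pin the azimuth origin."""
    out = np.empty((traj.n_frames, 2))
    for f in range(traj.n_frames):
        va = helix_vector(traj.xyz[f], traj.topology, axis_helix)
        vt = helix_vector(traj.xyz[f], traj.topology, target_helix)
        el, az, _ = elevation_azimuth(va, plane_reference, vt)
        out[f] = (el, az)
    return out


def orientation_frequency_map(traj: Trajectory, axis_helix: HelixDefinition,
                              target_helix: HelixDefinition, bins=36,
                              plane_reference=(1.0, 0.0, 0.0)) -> SamplingMap:
    """Frequency histogram over (azimuth, elevation); frequencies sum to 1."""
    angles = orientation_series(traj, axis_helix, target_helix,
                                plane_reference)
    az_edges = np.linspace(-180.0, 180.0, bins + 1)
    el_edges = np.linspace(-90.0, 90.0, bins + 1)
    counts, _, _ = np.histogram2d(angles[:, 1], angles[:, 0],
                                  bins=[az_edges, el_edges])
    return SamplingMap(az_edges, el_edges, counts / counts.sum(),
                       "azimuth_deg", "elevation_deg", normalized=True)
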