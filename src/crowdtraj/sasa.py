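"""Shrake-Rupley solvent-accessible surface area with a per-residue
ALL / SIDE / BB / POL / APOL decomposition.

The probe-inflated sphere of each atom is sampled on a deterministic
Fibonacci lattice (default 960 points, ~1% quadrature accuracy); a test
point is accessible when it lies outside every neighboring inflated sphere.
POL collects side-chain oxygens and nitrogens, APOL every other side-chain
atom, so POL + APOL = SIDE and SIDE + BB = ALL per residue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import Topology
from .constants import BONDI_RADII_NM, FALLBACK_RADIUS_NM

CLASSES = ("ALL", "SIDE", "BB", "POL", "APOL")


@dataclass
class SASAProfile:
    """Per-residue SASA (nm^2) in the five atom classes, plus totals."""

    residue_indices: np.ndarray
    areas: dict = field(default_factory=dict)  # class -> per-residue nm^2
    probe_radius: float = 0.14
    n_sphere_points: int = 960

    @property
    def totals(self) -> dict:
        return {c: float(a.sum()) for c, a in self.areas.items()}

    def to_dataframe(self):
        import pandas as pd
        df = pd.DataFrame({"residue": self.residue_indices + 1})  # 1-based
        for c in CLASSES:
            df[c] = self.areas[c]
        return df


def fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (golden-angle lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)])


def atomic_radii(topology: Topology, radii_table: dict | None = None,
                 strict: bool = False) -> np.ndarray:
    table = dict(BONDI_RADII_NM)
    if radii_table:
        table.update({k.upper(): v for k, v in radii_table.items()})
    out = np.empty(topology.n_atoms)
    for i, el in enumerate(topology.elements):
        key = str(el).upper()
        if key not in table:
            if strict:
                raise KeyError(f"no van der Waals radius for element {el!r}")
            out[i] = FALLBACK_RADIUS_NM
        else:
            out[i] = table[key]
    return out


def shrake_rupley(frame: np.ndarray, radii: np.ndarray,
                  probe: float = 0.14, n_sphere_points: int = 960
                  ) -> np.ndarray:
    """Per-atom accessible area (nm^2).

    area_i = (accessible points / total points) * 4*pi*(r_i + probe)^2
    """
    frame = np.asarray(frame, float)
    radii = np.asarray(radii, float)
    inflated = radii + probe
    sphere = fibonacci_sphere(n_sphere_points)
    rmax = inflated.max()
    tree = cKDTree(frame)
    areas = np.empty(len(frame))
    for i in range(len(frame)):
        pts = frame[i] + inflated[i] * sphere
        neighbors = [j for j in tree.query_ball_point(frame[i],
                                                      inflated[i] + rmax)
                     if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        eps = 1e-9
        for j in neighbors:
            d2 = np.sum((pts - frame[j]) ** 2, axis=1)
            # points exactly on a neighbor's surface (degenerate coincident
            # spheres) are assigned to the lower-index atom once, so the
            # union area is counted exactly one time
            if j < i:
                accessible &= d2 > inflated[j] ** 2 + eps
            else:
                accessible &= d2 >= inflated[j] ** 2 - eps
            if not accessible.any():
                break
        areas[i] = (accessible.mean()) * 4 * np.pi * inflated[i] ** 2
    return areas


def sasa(frame: np.ndarray, topology: Topology,
         radii_table: dict | None = None, probe: float = 0.14,
         n_sphere_points: int = 960) -> SASAProfile:
    """Per-residue SASA decomposition of one frame.

    Backbone membership comes from the topology (N, CA, C, O, OXT names);
    POL = side-chain O and N atoms, APOL = all other side-chain atoms,
    following an element-only polarity definition (histidine side-chain N
    counts as polar).
    """
    radii = atomic_radii(topology, radii_table)
    per_atom = shrake_rupley(frame, radii, probe, n_sphere_points)
    res_ids = np.unique(topology.residue_indices)
    bb = topology.is_backbone
    side = ~bb
    polar_el = np.array([str(e).upper() in ("O", "N")
                         for e in topology.elements])
    masks = {
        "ALL": np.ones(topology.n_atoms, dtype=bool),
        "BB": bb,
        "SIDE": side,
        "POL": side & polar_el,
        "APOL": side & ~polar_el,
    }
    areas = {}
    for cls, mask in masks.items():
        vals = np.zeros(len(res_ids))
        for k, r in enumerate(res_ids):
            sel = (topology.residue_indices == r) & mask
            vals[k] = per_atom[sel].sum()
        areas[cls] = vals
    return SASAProfile(res_ids, areas, probe, n_sphere_points)


def sasa_series(traj, topology: Topology | None = None, **kwargs
                ) -> list[SASAProfile]:
    top = topology or traj.topology
    return [sasa(traj.xyz[f], top, **kwargs) for f in range(traj.n_frames)]
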