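"""Synthetic trajectory generators with known ground truth.

Each generator emulates one statistical feature of a crowded-protein
simulation — diffusing centers of mass, near-Gaussian fluctuations about a
mean structure, helices with planted orientations, transient coil contacts,
discrete conformer switching, and a dense multi-chain box — so that every
estimator in the package can be validated against a planted truth.

All generators are bit-reproducible given (spec, seed): randomness flows
through one ``numpy.random.Generator`` per call, no global state.  Each
returns ``(Trajectory, manifest)`` where the manifest is a JSON-serializable
dict carrying the spec and the planted ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import Molecule, Topology, Trajectory, wrap_into_box
from .constants import MEAN_RESIDUE_MASS_AMU, AMU_KG, NM3_PER_L

HELIX_RADIUS_NM = 0.23
CA_BOND_NM = 0.38


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class BrownianSpec:
    """Free Brownian point particles in a periodic box."""

    n_particles: int = 100
    d_true: float = 1e-3        # nm^2/ps
    dt: float = 1.0             # ps
    n_steps: int = 10_000
    box: tuple = (10.0, 10.0, 10.0)  # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_true < 0 or self.dt <= 0:
            raise ValueError("need d_true >= 0 and dt > 0")
        step = np.sqrt(2 * self.d_true * self.dt)
        if step >= min(self.box) / 2:
            raise ValueError("per-step displacement exceeds half box")


@dataclass
class GaussianEnsembleSpec:
    """Zero-mean Gaussian fluctuations with planted mass-weighted
    covariance eigenvalues (amu*nm^2)."""

    eigenvalues: tuple = (0.01, 0.02, 0.03)
    masses: tuple = ()          # amu per coordinate; default 12 amu
    temperature: float = 300.0
    n_frames: int = 10_000
    seed: int = 0
    mix: bool = True            # apply a random orthogonal mode mixing

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, float)
        if np.any(ev <= 0):
            raise ValueError("planted eigenvalues must be > 0")
        if len(ev) % 3 != 0:
            raise ValueError("dimension must be a multiple of 3 (atoms x 3)")
        if not self.masses:
            self.masses = tuple([12.0] * len(ev))
        if len(self.masses) != len(ev):
            raise ValueError("one mass per coordinate required")
        if self.n_frames < 10 * len(ev):
            raise ValueError("n_frames must be >= 10 x dimension")


@dataclass
class HelixPairSpec:
    """Two ideal helices; the second planted at (elevation, azimuth)
    relative to the first helix's axis frame."""

    n_res: int = 12
    rise: float = 0.15          # nm per residue
    twist: float = 100.0        # degrees per residue
    elevation: float = 0.0      # degrees, planted
    azimuth: float = 0.0        # degrees, planted
    noise_sigma: float = 0.0    # nm, isotropic Gaussian per Calpha
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-90.0 <= self.elevation <= 90.0):
            raise ValueError("elevation must lie in [-90, 90] degrees")
        if not (-180.0 < self.azimuth <= 180.0):
            raise ValueError("azimuth must lie in (-180, 180] degrees")
        if self.n_res < 4:
            raise ValueError("need at least 4 residues per helix")


@dataclass
class TwoStateSpec:
    """Discrete two-conformer switching (symmetric Markov chain) with
    Gaussian positional noise around the active conformer."""

    conformer_a: np.ndarray = None
    conformer_b: np.ndarray = None
    mean_dwell: float = 50.0    # frames
    noise_sigma: float = 0.02   # nm
    n_frames: int = 1000
    dt: float = 20.0            # ps between stored frames
    cluster_cutoff: float = 0.15  # nm, the cutoff the fixture is built for
    seed: int = 0

    def __post_init__(self) -> None:
        from .descriptors import kabsch_superpose
        a = np.asarray(self.conformer_a, float)
        b = np.asarray(self.conformer_b, float)
        if a.shape != b.shape or a.ndim != 2:
            raise ValueError("conformers must be equal-shape (n, 3) arrays")
        self.conformer_a, self.conformer_b = a, b
        _, _, rmsd = kabsch_superpose(b, a)
        if rmsd <= 2 * self.cluster_cutoff:
            raise ValueError(
                f"conformers too similar (RMSD {rmsd:.3f} nm <= "
                f"2 x cutoff {self.cluster_cutoff} nm)")
        if self.noise_sigma >= self.cluster_cutoff / 4:
            raise ValueError("noise_sigma must be < cutoff/4")
        if self.mean_dwell < 1:
            raise ValueError("mean_dwell must be >= 1 frame")


@dataclass
class ChainSpec:
    n_res: int
    kind: str = "coil"          # coil | helix
    copies: int = 1


@dataclass
class CrowdedBoxSpec:
    """A dense box of Calpha-bead chains at a target mass concentration."""

    chains: tuple = (ChainSpec(30, "coil", 4), ChainSpec(20, "helix", 4))
    concentration: float = 192.0   # g/L
    n_frames: int = 1
    d_chain: float = 5e-4          # nm^2/ps rigid-chain diffusion, if animated
    dt: float = 20.0               # ps
    bead_jitter: float = 0.02      # nm per-bead noise per frame
    min_separation: float = 0.3    # nm bead-bead clash distance
    seed: int = 0
    max_retries: int = 2000

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("target concentration must be > 0 g/L")
        if not self.chains:
            raise ValueError("at least one chain spec required")


# ---------------------------------------------------------------------------
# small builders
# ---------------------------------------------------------------------------

def _bead_topology(chain_lengths, resname="GLY", name="CA") -> Topology:
    """Calpha-bead topology: one bead per residue, one molecule per chain."""
    names, resnames, resid, molid = [], [], [], []
    r = 0
    for m, n_res in enumerate(chain_lengths):
        for _ in range(n_res):
            names.append(name)
            resnames.append(resname)
            resid.append(r)
            molid.append(m)
            r += 1
    n = len(names)
    return Topology(np.array(names, object), np.array(["C"] * n, object),
                    np.full(n, MEAN_RESIDUE_MASS_AMU), np.array(resid),
                    np.array(resnames, object), np.array(molid))


def build_helix(n_res: int, rise: float = 0.15, twist: float = 100.0
                ) -> np.ndarray:
    """Ideal alpha-helical Calpha trace along +z, centered at the origin.

    Radius 0.23 nm, ``rise`` nm and ``twist`` degrees per residue; with the
    defaults the consecutive Calpha-Calpha distance is ~0.38 nm.  The trace
    is rigidly rotated so that its first principal axis lies exactly on +z:
    for a finite helix with fractional turns the principal axis tilts away
    from the screw axis (the incomplete turn biases the centroid), and
    aligning it up front makes the construction its own orientation oracle.
    """
    if n_res < 4:
        raise ValueError("a helix needs at least 4 residues")
    i = np.arange(n_res)
    theta = np.deg2rad(twist) * i
    xyz = np.column_stack([HELIX_RADIUS_NM * np.cos(theta),
                           HELIX_RADIUS_NM * np.sin(theta),
                           rise * i])
    xyz = xyz - xyz.mean(axis=0)
    cov = xyz.T @ xyz
    _, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    if np.dot(axis, xyz[-1] - xyz[0]) < 0:
        axis = -axis
    return xyz @ _rotation_to_direction(axis)  # R.T @ pts == pts @ R


def _rotation_to_direction(d: np.ndarray) -> np.ndarray:
    """A proper rotation taking +z onto unit vector d."""
    z = np.array([0.0, 0.0, 1.0])
    d = d / np.linalg.norm(d)
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


def direction_from_angles(elevation: float, azimuth: float) -> np.ndarray:
    """Unit vector at (elevation, azimuth) degrees in the frame where the
    axis is +z and azimuth zero is +x."""
    el, az = np.deg2rad(elevation), np.deg2rad(azimuth)
    return np.array([np.cos(el) * np.cos(az),
                     np.cos(el) * np.sin(az),
                     np.sin(el)])


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def gen_brownian(spec: BrownianSpec) -> tuple[Trajectory, dict]:
    """Free Brownian motion: per-step displacement ~ N(0, 2*D*dt) per axis,
    wrapped into the box.  One molecule per particle."""
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, float)
    n, T = spec.n_particles, spec.n_steps + 1
    start = rng.uniform(0, box, size=(n, 3))
    steps = rng.normal(0.0, np.sqrt(2 * spec.d_true * spec.dt),
                       size=(T - 1, n, 3))
    path = np.concatenate([start[None], start[None] + np.cumsum(steps, 0)])
    xyz = wrap_into_box(path, box)
    top = _bead_topology([1] * n, resname="BRW")
    traj = Trajectory(top, xyz, np.arange(T) * spec.dt, box)
    manifest = {"generator": "brownian", "spec": asdict(spec),
                "ground_truth": {"D_nm2_per_ps": spec.d_true}}
    return traj, manifest


def gen_gaussian_ensemble(spec: GaussianEnsembleSpec) -> tuple[Trajectory, dict]:
    """Frames drawn from a zero-mean Gaussian whose mass-weighted covariance
    has exactly the requested eigenvalue spectrum.

    In mass-weighted coordinates y = M^(1/2) x the covariance is
    U diag(lambda) U^T with U a seeded random orthogonal matrix (identity if
    ``mix`` is off), so the planted spectrum is recoverable by the entropy
    module's covariance estimator (without rigid-body removal)."""
    rng = np.random.default_rng(spec.seed)
    ev = np.asarray(spec.eigenvalues, float)
    d = len(ev)
    m = np.asarray(spec.masses, float)
    if spec.mix:
        q, _ = np.linalg.qr(rng.normal(size=(d, d)))
        u = q
    else:
        u = np.eye(d)
    y = rng.normal(size=(spec.n_frames, d)) * np.sqrt(ev)
    x = (y @ u.T) / np.sqrt(m)
    n_atoms = d // 3
    # a fixed spread-out mean structure keeps atoms distinguishable
    base = np.arange(n_atoms)[:, None] * np.array([1.0, 0.0, 0.0])
    xyz = x.reshape(spec.n_frames, n_atoms, 3) + base
    top = _bead_topology([n_atoms], resname="GAU")
    top.masses = m.reshape(n_atoms, 3)[:, 0].copy()
    traj = Trajectory(top, xyz, np.arange(spec.n_frames, dtype=float),
                      np.array([1000.0, 1000.0, 1000.0]))
    manifest = {"generator": "gaussian_ensemble",
                "spec": {**asdict(spec),
                         "eigenvalues": list(map(float, ev)),
                         "masses": list(map(float, m))},
                "ground_truth": {"eigenvalues_amu_nm2": list(map(float, ev)),
                                 "temperature_K": spec.temperature}}
    return traj, manifest


def build_helix_pair(spec: HelixPairSpec) -> tuple[Trajectory, dict]:
    """Helix 1 on the +z reference axis; helix 2 rotated so that its axis
    sits at the planted (elevation, azimuth) in the frame (z = helix-1 axis,
    x = lab x), then displaced to avoid overlap.  Gaussian noise optional."""
    rng = np.random.default_rng(spec.seed)
    h1 = build_helix(spec.n_res, spec.rise, spec.twist)
    d = direction_from_angles(spec.elevation, spec.azimuth)
    rot = _rotation_to_direction(d)
    h2 = build_helix(spec.n_res, spec.rise, spec.twist) @ rot.T
    h2 = h2 + np.array([2.5, 0.0, 0.0])  # lateral offset, nm
    xyz = np.vstack([h1, h2])
    if spec.noise_sigma > 0:
        xyz = xyz + rng.normal(0.0, spec.noise_sigma, xyz.shape)
    top = _bead_topology([spec.n_res, spec.n_res], resname="ALA")
    traj = Trajectory(top, xyz[None], np.array([0.0]),
                      np.array([100.0, 100.0, 100.0]))
    manifest = {"generator": "helix_pair", "spec": asdict(spec),
                "ground_truth": {"elevation_deg": spec.elevation,
                                 "azimuth_deg": spec.azimuth,
                                 "frame_plane": [1.0, 0.0, 0.0]}}
    return traj, manifest


def _fjc_directions(rng, n_steps: int) -> np.ndarray:
    """Uniform random unit vectors (freely jointed chain steps)."""
    v = rng.normal(size=(n_steps, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _coil_frame(rng, n_res: int, bond: float, planted) -> np.ndarray:
    """One freely jointed chain conformation; sub-chains spanning planted
    pairs are resampled until the pair sits within 0.7 nm (inside the
    0.8 nm contact cutoff), keeping every bond exactly ``bond`` long."""
    dirs = _fjc_directions(rng, n_res - 1)
    for (i, j) in planted:
        for _ in range(100_000):
            sub = _fjc_directions(rng, j - i)
            if np.linalg.norm(bond * sub.sum(axis=0)) <= 0.7:
                dirs[i:j] = sub
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("planted-contact resampling did not converge")
    xyz = np.vstack([np.zeros(3), np.cumsum(bond * dirs, axis=0)])
    return xyz - xyz.mean(axis=0)


def gen_random_coil(n_res: int, n_frames: int = 100, bond: float = CA_BOND_NM,
                    seed: int = 0, planted_contact_pairs=()
                    ) -> tuple[Trajectory, dict]:
    """Freely jointed Calpha chain; each frame is an independent
    conformation.  Planted residue pairs are held within the 0.8 nm contact
    cutoff by conditional resampling of the intervening sub-chain.

    Planted pairs must be separated by at least 3 residues and span
    non-overlapping residue intervals.
    """
    planted = sorted((min(i, j), max(i, j)) for i, j in planted_contact_pairs)
    for (i, j) in planted:
        if j - i < 3:
            raise ValueError(f"planted pair ({i},{j}) closer than 3 residues")
        if i < 0 or j >= n_res:
            raise ValueError(f"planted pair ({i},{j}) outside the chain")
    for (a, b), (c, d) in zip(planted, planted[1:]):
        if c < b:
            raise ValueError("overlapping planted intervals are infeasible")
    rng = np.random.default_rng(seed)
    xyz = np.array([_coil_frame(rng, n_res, bond, planted)
                    for _ in range(n_frames)])
    top = _bead_topology([n_res])
    traj = Trajectory(top, xyz, np.arange(n_frames, dtype=float) * 20.0,
                      np.array([1000.0, 1000.0, 1000.0]))
    manifest = {"generator": "random_coil",
                "spec": {"n_res": n_res, "n_frames": n_frames, "bond": bond,
                         "seed": seed},
                "ground_truth": {"planted_pairs": [list(p) for p in planted]}}
    return traj, manifest


def gen_two_state(spec: TwoStateSpec) -> tuple[Trajectory, dict]:
    """Hidden two-state Markov chain (switch probability 1/mean_dwell per
    frame); the emitted frame is the active conformer plus isotropic noise."""
    rng = np.random.default_rng(spec.seed)
    p = 1.0 / spec.mean_dwell
    states = np.empty(spec.n_frames, dtype=int)
    states[0] = 0
    flips = rng.random(spec.n_frames - 1) < p
    states[1:] = (np.cumsum(flips) + states[0]) % 2
    conf = np.stack([spec.conformer_a, spec.conformer_b])
    xyz = conf[states] + rng.normal(0.0, spec.noise_sigma,
                                    (spec.n_frames,) + spec.conformer_a.shape)
    top = _bead_topology([len(spec.conformer_a)])
    traj = Trajectory(top, xyz, np.arange(spec.n_frames) * spec.dt,
                      np.array([1000.0, 1000.0, 1000.0]))
    manifest = {"generator": "two_state",
                "spec": {"mean_dwell": spec.mean_dwell,
                         "noise_sigma": spec.noise_sigma,
                         "n_frames": spec.n_frames, "dt": spec.dt,
                         "seed": spec.seed},
                "ground_truth": {"states": states.tolist(),
                                 "n_transitions": int(np.sum(flips)),
                                 "mean_dwell_frames": spec.mean_dwell}}
    return traj, manifest


def box_edge_for_concentration(total_mass_amu: float,
                               concentration_g_per_l: float) -> float:
    """Cubic box edge (nm) so that mass/volume equals the target g/L."""
    mass_g = total_mass_amu * AMU_KG * 1e3
    volume_l = mass_g / concentration_g_per_l
    return float((volume_l * NM3_PER_L) ** (1.0 / 3.0))


def build_crowded_box(spec: CrowdedBoxSpec) -> tuple[Trajectory, dict]:
    """Dense box of Calpha-bead chains at the target concentration.

    The cubic edge L is fixed analytically from the total chain mass, so the
    achieved concentration equals the target by construction; chains are
    then placed with random positions/orientations under a hard-sphere
    (0.3 nm) clash rejection.  With ``n_frames > 1`` the chains undergo
    rigid-body Brownian motion plus small per-bead jitter, giving the
    pipeline realistic contacts and diffusion to measure.
    """
    rng = np.random.default_rng(spec.seed)
    lengths, kinds = [], []
    for ch in spec.chains:
        for _ in range(ch.copies):
            lengths.append(ch.n_res)
            kinds.append(ch.kind)
    total_mass = MEAN_RESIDUE_MASS_AMU * sum(lengths)
    L = box_edge_for_concentration(total_mass, spec.concentration)
    box = np.array([L, L, L])

    placed: list[np.ndarray] = []
    for n_res, kind in zip(lengths, kinds):
        if kind == "helix":
            base = build_helix(n_res)
        elif kind == "coil":
            base = _coil_frame(rng, n_res, CA_BOND_NM, [])
        else:
            raise ValueError(f"unknown chain kind {kind!r}")
        ok = False
        for _ in range(spec.max_retries):
            rot = _rotation_to_direction(_fjc_directions(rng, 1)[0])
            cand = base @ rot.T + rng.uniform(0, L, 3)
            if _clashes(cand, placed, box, spec.min_separation):
                continue
            placed.append(cand)
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place a {n_res}-residue chain without clashes "
                f"after {spec.max_retries} tries (box {L:.2f} nm)")

    frame0 = np.vstack(placed)
    frames = [frame0]
    offsets = np.zeros((len(placed), 3))
    sizes = np.array(lengths)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    for _ in range(spec.n_frames - 1):
        offsets = offsets + rng.normal(
            0.0, np.sqrt(2 * spec.d_chain * spec.dt), offsets.shape)
        f = frame0.copy()
        for k, (s, n_res) in enumerate(zip(starts, sizes)):
            f[s:s + n_res] += offsets[k]
        f += rng.normal(0.0, spec.bead_jitter, f.shape)
        frames.append(f)
    xyz = wrap_into_box(np.array(frames), box)
    top = _bead_topology(lengths)
    traj = Trajectory(top, xyz, np.arange(spec.n_frames) * spec.dt, box)
    achieved = (total_mass * AMU_KG * 1e3) / (L ** 3 / NM3_PER_L)
    manifest = {
        "generator": "crowded_box",
        "spec": {"concentration_g_per_l": spec.concentration,
                 "n_frames": spec.n_frames, "seed": spec.seed,
                 "chains": [asdict(c) for c in spec.chains]},
        "ground_truth": {"box_edge_nm": L,
                         "achieved_concentration_g_per_l": float(achieved),
                         "total_mass_amu": float(total_mass),
                         "d_chain_nm2_per_ps": spec.d_chain,
                         "chain_kinds": kinds,
                         "chain_lengths": lengths},
    }
    return traj, manifest


def _clashes(cand, placed, box, min_sep) -> bool:
    from scipy.spatial import cKDTree
    w = wrap_into_box(cand, box)
    for other in placed:
        tree = cKDTree(wrap_into_box(other, box), boxsize=box)
        if tree.query_ball_point(w, min_sep, return_length=True).sum() > 0:
            return True
    return False


def save_manifest(manifest: dict, path) -> None:
    """Write the ground-truth sidecar next to an emitted trajectory."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))
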