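"""End-to-end orchestration: run every analysis stage over one or more
environments (water / PEG / protein-crowded), emit self-describing CSV/JSON
tables, and aggregate the disorder-vs-effect trend.

A "report bundle" is a directory of plain-text tables plus a manifest that
records the parameters, input hashes and stage outputs, so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import contacts as ct
from . import clustering as cl
from . import dynamics as dyn
from . import entropy as ent
from . import descriptors as desc
from .core import Trajectory
from .constants import WATER_VISCOSITY_300K, DEFAULT_RESIDUE_CLASSES
from .synthetic import CrowdedBoxSpec, ChainSpec, build_crowded_box

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class AnalysisConfig:
    """Parameters of a full analysis run; defaults mirror the standard
    protocol (0.8 nm contacts, 0.15/0.35 nm two-step clustering, 20 ps
    stride, water viscosity for the finite-size term)."""

    environments: dict = field(default_factory=dict)
    contact_cutoff: float = 0.8
    cluster_cutoff1: float = 0.15
    cluster_cutoff2: float = 0.35
    change_cutoff: float = 0.15
    msd_window_ps: float | None = None
    temperature: float = 300.0
    viscosity: float = WATER_VISCOSITY_300K
    entropy_window: tuple = (0.5, 1.0)
    residue_classes: dict = field(default_factory=lambda: dict(
        DEFAULT_RESIDUE_CLASSES))
    disorder_percent: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for c in (self.contact_cutoff, self.cluster_cutoff1,
                  self.cluster_cutoff2, self.change_cutoff):
            if c <= 0:
                raise ValueError("cutoffs must be positive")
        if len(set(self.environments)) != len(self.environments):
            raise ValueError("environment labels must be unique")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "entropy_window" in raw:
            raw["entropy_window"] = tuple(raw["entropy_window"])
        return cls(**raw)


def _load_environment(label: str, spec: dict, seed: int
                      ) -> tuple[Trajectory, dict]:
    """An environment is either file paths or an inline synthetic box."""
    if "synthetic" in spec:
        s = dict(spec["synthetic"])
        chains = tuple(ChainSpec(**c) for c in s.pop("chains"))
        box_spec = CrowdedBoxSpec(chains=chains, seed=s.pop("seed", seed), **s)
        return build_crowded_box(box_spec)
    from .io import read_structure, read_trajectory
    top, ref = read_structure(spec["structure"])
    if "trajectory" in spec:
        traj = read_trajectory(spec["trajectory"], top,
                               structure_path=spec["structure"],
                               dt=spec.get("dt"))
    else:
        traj = ref
    return traj, {"structure": str(spec["structure"])}


def run_pipeline(config: AnalysisConfig, out_dir) -> dict:
    """Run all analysis stages per environment and write the report bundle.

    Stage failures are logged and do not abort independent stages; the
    manifest lists which stages completed.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": _config_record(config), "environments": {},
                "stages": {}, "failed_stages": {}}
    trajs: dict[str, Trajectory] = {}
    for label, spec in config.environments.items():
        traj, info = _load_environment(label, spec, config.seed)
        trajs[label] = traj
        manifest["environments"][label] = info

    stages = {
        "descriptors": _stage_descriptors,
        "contacts": _stage_contacts,
        "clusters": _stage_clusters,
        "helix": _stage_helix,
        "diffusion": _stage_diffusion,
        "entropy": _stage_entropy,
    }
    results: dict = {}
    for name, fn in stages.items():
        try:
            results[name] = fn(trajs, config, out, manifest)
        except Exception as exc:  # keep independent stages running
            log.error("stage %s failed: %s", name, exc)
            manifest["failed_stages"][name] = str(exc)
    try:
        results["trend"] = _stage_trend(trajs, config, out, manifest, results)
    except Exception as exc:
        log.error("stage trend failed: %s", exc)
        manifest["failed_stages"]["trend"] = str(exc)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["ok"] = not manifest["failed_stages"]
    return manifest


def _config_record(config: AnalysisConfig) -> dict:
    rec = asdict(config)
    rec["entropy_window"] = list(config.entropy_window)
    for env, spec in rec["environments"].items():
        for key in ("structure", "trajectory"):
            if key in spec and Path(spec[key]).exists():
                spec[f"{key}_sha1"] = _sha1(spec[key])
    return rec


def _sha1(path) -> str:
    h = hashlib.sha1()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict, stage: str) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    manifest["stages"].setdefault(stage, []).append(path.name)


def _chain_residues(traj: Trajectory) -> dict:
    top = traj.topology
    return {m.molecule_id: np.arange(m.first_residue, m.last_residue + 1)
            for m in top.molecules}


def _stage_descriptors(trajs, config, out, manifest):
    rows = []
    for env, traj in trajs.items():
        ref = traj.xyz[0]
        rmsd = desc.rmsd_series(traj, ref)
        rg = desc.rg_series(traj)
        for f in range(traj.n_frames):
            rows.append({"environment": env, "time_ps": traj.times[f],
                         "rmsd_nm": rmsd[f], "rg_nm": rg[f]})
        fl = desc.rmsf(traj)
        per_res = pd.DataFrame({
            "environment": env,
            "residue": traj.topology.residue_indices + 1,
            "rmsf_nm": fl})
        _write(per_res, out / f"rmsf_{env}.csv", manifest, "descriptors")
        smap = desc.sampling_map(rmsd, rg, bins=20,
                                 x_label="rmsd_nm", y_label="rg_nm")
        _write(smap.to_dataframe(), out / f"sampling_map_{env}.csv",
               manifest, "descriptors")
    df = pd.DataFrame(rows)
    _write(df, out / "per_frame_descriptors.csv", manifest, "descriptors")
    return df


def _stage_contacts(trajs, config, out, manifest):
    summary = []
    for env, traj in trajs.items():
        chains = _chain_residues(traj)
        first = min(chains)
        others = np.concatenate([r for m, r in chains.items() if m != first]) \
            if len(chains) > 1 else np.array([], dtype=int)
        cmap = ct.contact_map(traj, chains[first],
                              cutoff=config.contact_cutoff)
        _write(cmap.to_long_dataframe(),
               out / f"contact_map_{env}_chain{first}.csv",
               manifest, "contacts")
        n_explored, frac = ct.explored_contacts(
            traj, chains[first], cutoff=config.contact_cutoff, cmap=cmap)
        inter_pct = (ct.interprotein_fraction(
            traj, chains[first], others, cutoff=config.contact_cutoff)
            if len(others) else 0.0)
        names = [str(traj.topology.residue_names[
            np.flatnonzero(traj.topology.residue_indices == r)[0]])
            for r in cmap.residues_a]
        comp = ct.class_composition(cmap, names,
                                    scheme=config.residue_classes)
        summary.append({"environment": env, "chain": first,
                        "explored_contacts": n_explored,
                        "explored_fraction": frac,
                        "interprotein_pct": inter_pct,
                        **{f"class_{k}_pct": v
                           for k, v in comp.contact_shares.items()}})
    df = pd.DataFrame(summary)
    _write(df, out / "contact_summary.csv", manifest, "contacts")
    return df


def _stage_clusters(trajs, config, out, manifest):
    first_chain = {env: min(_chain_residues(t)) for env, t in trajs.items()}
    sel = {env: t.topology.calpha(molecule_id=first_chain[env])
           for env, t in trajs.items()}
    rows = []
    for env, traj in trajs.items():
        timing = cl.conformational_change_times(
            traj, cutoff=config.change_cutoff, selection=sel[env])
        rows.append({"environment": env, **{k: v for k, v in timing.items()}})
    df = pd.DataFrame(rows)
    _write(df, out / "conformational_changes.csv", manifest, "clusters")
    if len(trajs) >= 2:
        joint, _ = cl.two_step_cluster(
            trajs, config.cluster_cutoff1, config.cluster_cutoff2,
            selection=next(iter(sel.values())))
        overlaps = cl.environment_overlap(joint)
        orows = [{"env_a": a, "env_b": b, **v}
                 for (a, b), v in overlaps.items()]
        _write(pd.DataFrame(orows), out / "environment_overlap.csv",
               manifest, "clusters")
    else:
        log.info("single environment: overlap stage skipped")
    return df


def _stage_helix(trajs, config, out, manifest):
    from .helix import HelixDefinition, orientation_series
    rows = []
    for env, traj in trajs.items():
        helical = [m for m in traj.topology.molecules
                   if m.last_residue - m.first_residue + 1 >= 4]
        if len(helical) < 2:
            continue
        h1 = HelixDefinition("h1", helical[0].first_residue,
                             helical[0].last_residue)
        h2 = HelixDefinition("h2", helical[1].first_residue,
                             helical[1].last_residue)
        angles = orientation_series(traj, h1, h2)
        for f, (el, az) in enumerate(angles):
            rows.append({"environment": env, "time_ps": traj.times[f],
                         "elevation_deg": el, "azimuth_deg": az})
    df = pd.DataFrame(rows)
    if len(df):
        _write(df, out / "helix_orientation.csv", manifest, "helix")
    return df


def _stage_diffusion(trajs, config, out, manifest):
    frames = []
    for env, traj in trajs.items():
        if traj.n_frames < 30:
            log.info("environment %s too short for diffusion; skipped", env)
            continue
        groups = {"chains": [m.molecule_id for m in traj.topology.molecules]}
        res = dyn.diffusion_table(
            traj, groups,
            windows_ps={"chains": config.msd_window_ps},
            temperature=config.temperature, viscosity=config.viscosity)
        df = dyn.diffusion_table_dataframe(res)
        df.insert(0, "environment", env)
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    df = pd.concat(frames, ignore_index=True)
    _write(df, out / "diffusion_table.csv", manifest, "diffusion")
    return df


def _stage_entropy(trajs, config, out, manifest):
    rows = []
    for env, traj in trajs.items():
        res = ent.backbone_entropy(traj, config.temperature,
                                   window=config.entropy_window)
        rows.append({"environment": env,
                     "s_j_per_mol_k": res.s_j_per_mol_k,
                     "s_kb": res.s_kb,
                     "n_modes": len(res.eigenvalues),
                     "selection": res.selection_label})
    df = pd.DataFrame(rows)
    _write(df, out / "entropy_summary.csv", manifest, "entropy")
    return df


def _stage_trend(trajs, config, out, manifest, results):
    """Aggregate per-environment effects against intrinsic disorder.

    Disorder (an external predictor output) is supplied per environment
    label in the config; the effect columns are taken from the stages that
    already ran: % inter-protein contacts, explored-contact fraction,
    backbone entropy and conformational-change count.
    """
    keys = [k for k in config.disorder_percent if k in trajs]
    if len(keys) < 3:
        log.info("fewer than 3 labeled proteins: trend stage skipped")
        return pd.DataFrame()
    table = pd.DataFrame({"protein": keys,
                          "disorder_pct": [config.disorder_percent[k]
                                           for k in keys]})
    merges = [("contacts", ["interprotein_pct", "explored_fraction"]),
              ("entropy", ["s_kb"]),
              ("clusters", ["n_transitions"])]
    for stage, cols in merges:
        df = results.get(stage)
        if df is None or not len(df):
            continue
        sub = df[["environment"] + [c for c in cols if c in df.columns]]
        table = table.merge(sub, left_on="protein", right_on="environment",
                            how="left").drop(columns="environment")
    stats = disorder_trend(table, seed=config.seed)
    _write(table, out / "trend_table.csv", manifest, "trend")
    _write(stats, out / "disorder_trend.csv", manifest, "trend")
    return stats


def build_trend_table(config: AnalysisConfig,
                      effects: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rows: one per protein; columns: disorder % plus effect columns."""
    df = pd.DataFrame({"protein": list(config.disorder_percent),
                       "disorder_pct": list(
                           config.disorder_percent.values())})
    if effects is not None:
        df = df.merge(effects, on="protein")
    return df


def disorder_trend(table: pd.DataFrame, disorder_col: str = "disorder_pct",
                   n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Spearman rank correlation of every effect column against disorder,
    with a one-sided permutation p-value (exhaustive for n <= 6 proteins).

    The p-value is the fraction of label permutations whose correlation is
    at least as extreme, in the observed direction, as the measured one.
    """
    from scipy.stats import spearmanr
    x = table[disorder_col].to_numpy(float)
    n = len(x)
    if n < 3:
        raise ValueError("trend needs at least 3 proteins")
    rng = np.random.default_rng(seed)
    rows = []
    effect_cols = [c for c in table.columns
                   if c not in (disorder_col, "protein")]
    for col in effect_cols:
        y = table[col].to_numpy(float)
        if np.all(y == y[0]) or np.all(x == x[0]):
            rows.append({"effect": col, "spearman_rho": np.nan,
                         "p_value": np.nan, "constant_column": True})
            continue
        rho = spearmanr(x, y).statistic
        if n <= 6:
            perms = list(itertools.permutations(range(n)))
        else:
            perms = [rng.permutation(n) for _ in range(n_perm)]
        null = np.array([spearmanr(x, y[list(p)]).statistic for p in perms])
        if rho >= 0:
            p = float(np.mean(null >= rho - 1e-12))
        else:
            p = float(np.mean(null <= rho + 1e-12))
        rows.append({"effect": col, "spearman_rho": float(rho),
                     "p_value": p, "constant_column": False})
    return pd.DataFrame(rows)
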