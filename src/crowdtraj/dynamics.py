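"""Center-of-mass MSD, Einstein-relation self-diffusion, and the
finite-size (periodic box) correction.

For free 3-D diffusion the mean square displacement grows as
MSD(tau) = 6 D tau; D is fit as slope/6 over a window of lag times.  A
diffusion coefficient measured under periodic boundaries underestimates
the infinite-dilution value because of hydrodynamic self-interaction with
the images; the additive correction is

    D0 = D_pbc + kB T xi / (6 pi eta L),   xi = 2.837297

with eta the solvent viscosity and L the cubic box edge (Yeh-Hummer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Trajectory, unwrapped_com_series
from .constants import (KB_J_PER_K, NM_M, XI_CUBIC,
                        NM2_PER_PS_TO_UM2_PER_S, M2_PER_S_TO_UM2_PER_S,
                        WATER_VISCOSITY_300K)


@dataclass
class MSDCurve:
    """Ensemble- and time-origin-averaged mean square displacement."""

    lags: np.ndarray       # ps
    msd: np.ndarray        # nm^2
    n_origins: np.ndarray  # time origins averaged per lag
    window: float          # ps

    def __post_init__(self) -> None:
        if self.msd[0] != 0.0:
            raise ValueError("MSD at zero lag must be 0")


@dataclass
class DiffusionResult:
    """Self-diffusion with and without the finite-size correction."""

    d_pbc_um2_s: float
    d_corrected_um2_s: float | None
    fit_range_ps: tuple
    slope_stderr: float
    r_squared: float
    per_molecule_um2_s: np.ndarray | None = None
    group_std_um2_s: float | None = None
    diagnostics: dict = field(default_factory=dict)


def msd(series: np.ndarray, dt: float, window: float | None = None,
        max_lag: int | None = None, box: np.ndarray | None = None
        ) -> MSDCurve:
    """MSD of one or more unwrapped 3-D coordinate series.

    ``series``: (n_frames, 3) or (n_molecules, n_frames, 3), nm, unwrapped.
    All time origins are used at every lag; with several molecules the
    average also runs over molecules.  If ``box`` is given, a consecutive
    jump above half a box edge raises (wrapped input).
    """
    s = np.asarray(series, float)
    if s.ndim == 2:
        s = s[None]
    n_frames = s.shape[1]
    if box is not None:
        jumps = np.abs(np.diff(s, axis=1))
        if np.any(jumps > np.asarray(box) / 2):
            raise ValueError("consecutive jump exceeds half the box: input "
                             "looks wrapped; unwrap before computing MSD")
    if window is not None:
        max_lag = int(round(window / dt))
    if max_lag is None:
        max_lag = n_frames // 2
    max_lag = min(max_lag, n_frames - 1)
    lags = np.arange(max_lag + 1)
    vals = _msd_all_origins(s, max_lag)
    n_origins = n_frames - lags
    return MSDCurve(lags * dt, vals, n_origins, max_lag * dt)


def _msd_all_origins(s: np.ndarray, max_lag: int) -> np.ndarray:
    """Exact all-origin MSD via the FFT autocorrelation identity.

    msd(k) = [sum_t (|r_t|^2 + |r_{t+k}|^2) - 2 sum_t r_t . r_{t+k}]
             / (T - k), with the dot-product sum evaluated by FFT.
    """
    p, t, _ = s.shape
    nfft = 1 << int(np.ceil(np.log2(2 * t)))
    f = np.fft.rfft(s, n=nfft, axis=1)
    acf = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, :t, :].sum(axis=2)
    d2 = np.sum(s * s, axis=2)
    css = np.cumsum(d2, axis=1)
    total = css[:, -1][:, None]
    k = np.arange(max_lag + 1)
    lead = css[:, t - 1 - k]
    trail = total - np.where(k > 0, css[:, np.maximum(k - 1, 0)], 0.0)
    vals = (lead + trail - 2.0 * acf[:, :max_lag + 1]) / (t - k)
    vals = vals.mean(axis=0)
    vals[0] = 0.0  # exact by definition; kills FFT round-off
    return np.maximum(vals, 0.0)


def einstein_diffusion(curve: MSDCurve, fit_fraction=(0.1, 0.9),
                       r2_threshold: float = 0.9) -> DiffusionResult:
    """Fit D = slope/6 from the linear regime of an MSD curve.

    The fit window is a fraction of the curve's lag range (default the
    central 10-90%).  Linearity is judged on the log-log exponent of the
    curve in the window (1 for diffusion, 2 for ballistic motion): an
    exponent off unity by more than 0.2, or a plain R^2 below threshold,
    raises the ``poor_linearity`` diagnostic; a negative slope reports
    D = 0 with its own flag.
    """
    lo = fit_fraction[0] * curve.lags[-1]
    hi = fit_fraction[1] * curve.lags[-1]
    mask = (curve.lags >= lo) & (curve.lags <= hi)
    if mask.sum() < 10:
        raise ValueError("fewer than 10 lags in the fit window")
    res = stats.linregress(curve.lags[mask], curve.msd[mask])
    d_nm2_ps = res.slope / 6.0
    pos = mask & (curve.lags > 0) & (curve.msd > 0)
    if pos.sum() >= 10:
        exponent = float(stats.linregress(np.log(curve.lags[pos]),
                                          np.log(curve.msd[pos])).slope)
    else:
        exponent = float("nan")
    diagnostics = {
        "poor_linearity": bool(
            (np.isfinite(exponent) and abs(exponent - 1.0) > 0.2)
            or res.rvalue ** 2 < r2_threshold),
        "negative_slope": bool(res.slope < 0),
        "msd_exponent": exponent,
    }
    if res.slope < 0:
        d_nm2_ps = 0.0
    return DiffusionResult(
        d_pbc_um2_s=d_nm2_ps * NM2_PER_PS_TO_UM2_PER_S,
        d_corrected_um2_s=None,
        fit_range_ps=(float(lo), float(hi)),
        slope_stderr=float(res.stderr or 0.0),
        r_squared=float(res.rvalue ** 2),
        diagnostics=diagnostics,
    )


def finite_size_correction(d_pbc_um2_s: float, temperature: float,
                           viscosity: float, box_edge_nm: float) -> float:
    """Finite-size-corrected D (um^2/s).

    Adds kB*T*xi / (6 pi eta L) with xi = 2.837297; temperature in K,
    viscosity in Pa*s, box edge in nm.
    """
    if box_edge_nm <= 0 or viscosity <= 0:
        raise ValueError("box edge and viscosity must be positive")
    corr_m2_s = (KB_J_PER_K * temperature * XI_CUBIC
                 / (6.0 * np.pi * viscosity * box_edge_nm * NM_M))
    return d_pbc_um2_s + corr_m2_s * M2_PER_S_TO_UM2_PER_S


def diffusion_table(traj: Trajectory, groups: dict,
                    windows_ps: dict | None = None,
                    temperature: float = 300.0,
                    viscosity: float = WATER_VISCOSITY_300K):
    """Per-group diffusion summary in the shape system x group.

    ``groups`` maps a group label to a list of molecule ids;
    ``windows_ps`` optionally sets a per-group MSD window (e.g. 1e4 ps for
    water, 2.5e4 ps for proteins).  Returns ``{label: DiffusionResult}``
    with per-molecule values, group mean and standard deviation (flagged
    not-applicable for single-molecule groups), and both raw and
    finite-size-corrected coefficients.
    """
    windows_ps = windows_ps or {}
    coms = unwrapped_com_series(traj)  # (n_mol, n_frames, 3)
    mol_ids = [m.molecule_id for m in traj.topology.molecules]
    box_edge = float(traj.boxes[0, 0])
    out = {}
    for label, members in groups.items():
        rows = [mol_ids.index(m) for m in members]
        window = windows_ps.get(label)
        per_mol = []
        for r in rows:
            curve = msd(coms[r], traj.dt, window=window)
            per_mol.append(einstein_diffusion(curve).d_pbc_um2_s)
        per_mol = np.array(per_mol)
        curve = msd(coms[rows], traj.dt, window=window)
        group_res = einstein_diffusion(curve)
        group_res.per_molecule_um2_s = per_mol
        group_res.group_std_um2_s = (float(per_mol.std(ddof=1))
                                     if len(per_mol) > 1 else None)
        if len(per_mol) == 1:
            group_res.diagnostics["std_not_applicable"] = True
        group_res.d_corrected_um2_s = finite_size_correction(
            group_res.d_pbc_um2_s, temperature, viscosity, box_edge)
        out[label] = group_res
    return out


def diffusion_table_dataframe(results: dict):
    import pandas as pd
    rows = []
    for label, r in results.items():
        rows.append({
            "group": label,
            "D_pbc_um2_s": r.d_pbc_um2_s,
            "D_corrected_um2_s": r.d_corrected_um2_s,
            "mean_per_molecule_um2_s": (float(r.per_molecule_um2_s.mean())
                                        if r.per_molecule_um2_s is not None
                                        else None),
            "std_um2_s": r.group_std_um2_s,
            "r_squared": r.r_squared,
        })
    return pd.DataFrame(rows)
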