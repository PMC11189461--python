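"""Measurements on states and trajectories of the constricted tubule.

Necks (sites of maximum constriction), the critical state (maximum elastic
energy preceding fission) and its activation energy, the inner/flank split
of that energy, fission detection and timing, and the normalized
Debye-corrected lumenal conductance used for comparison with real-time
electrophysiology of dynamin-coated tubules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dynamics import Trajectory, TrajectoryRecord
from .fields import AxisymmetricGrid, MidplaneContour
from .forcing import _as_coatset

__all__ = [
    "NeckAnalysis",
    "CriticalState",
    "ConductanceTrace",
    "analyze_necks",
    "detect_fission",
    "critical_state",
    "energy_split",
    "conductance",
    "conductance_trace",
    "trajectory_observables_frame",
    "fission_time",
]


@dataclass(frozen=True)
class NeckAnalysis:
    """Necks of a midplane contour.

    ``R_n`` is the global minimum midplane radius, ``R_c`` the radius at the
    coat center, ``D`` the distance between the two outermost necks (0 for
    a single neck) and ``neck_positions`` their axial locations.
    """

    neck_positions: tuple[float, ...]
    R_n: float
    R_c: float
    D: float
    n_necks: int


@dataclass(frozen=True)
class CriticalState:
    """State of maximum elastic energy preceding fission.

    ``dF_e`` is the activation energy: the elastic energy above the
    unperturbed tubule.  ``inner`` / ``flanks`` split dF_e between the
    region enclosed by the outermost necks and the rest of the tubule.
    """

    time: float
    dF_e: float
    necks: NeckAnalysis
    inner: float
    flanks: float
    record: TrajectoryRecord


@dataclass
class ConductanceTrace:
    """Normalized lumenal conductance G_n(t); 1 initially, 0 after closure."""

    times: np.ndarray
    G_n: np.ndarray
    lambda_D: float


def analyze_necks(contour: MidplaneContour, coats=None,
                  prominence: float = 0.5) -> NeckAnalysis:
    """Identify necks on a pre-fission contour.

    A local minimum of r(z) counts as a neck only when its (topographic)
    prominence is at least ``prominence`` nm, which suppresses grid-scale
    ripples; a perfect cylinder has no neck.  ``R_c`` is the radius at the
    (first) coat center, or at the deepest minimum when no coat is given.
    """
    from scipy.signal import find_peaks

    if contour.any_closed:
        raise ValueError("contour has severed columns; use fission observables")
    r = contour.r_mid
    z = contour.z
    necks, _props = find_peaks(-r, prominence=prominence)
    necks = list(necks)
    coatset = _as_coatset(coats) if coats is not None else None
    if coatset is not None and len(coatset.coats):
        z_c = coatset.coats[0].z_0
    elif necks:
        z_c = z[min(necks, key=lambda i: r[i])]
    else:
        z_c = z[np.argmin(r)]
    R_c = float(np.interp(z_c, z, r))
    if not necks:
        R = float(r.min())
        return NeckAnalysis(neck_positions=(), R_n=R, R_c=R_c, D=0.0, n_necks=0)
    positions = tuple(float(z[i]) for i in necks)
    R_n = float(min(r[i] for i in necks))
    D = max(positions) - min(positions) if len(positions) > 1 else 0.0
    return NeckAnalysis(neck_positions=positions, R_n=R_n, R_c=R_c,
                        D=float(D), n_necks=len(positions))


def detect_fission(grid: AxisymmetricGrid, phi: np.ndarray) -> tuple[bool, float | None]:
    """Fission flag and axial location (centroid of severed columns).

    The tubule is severed when the phi > 0 phase is disconnected along z,
    i.e. at least one z column is entirely phi < 0.
    """
    open_cols = (phi > 0.0).any(axis=0)
    if open_cols.all():
        return False, None
    z = grid.z_centers[~open_cols]
    return True, float(z.mean())


def critical_state(traj: Trajectory, coats=None,
                   prominence: float = 0.5) -> CriticalState | None:
    """State of maximum elastic energy over the pre-fission window.

    Returns None for trajectories that never reach fission (by definition
    there is no critical state when no fission occurs).
    """
    if traj.outcome != "fission":
        return None
    pre = traj.pre_fission_records()
    if not pre:
        return None
    Fe0 = traj.records[0].energy.F_e
    rec = max(pre, key=lambda r: r.energy.F_e)
    necks = analyze_necks(rec.contour, coats, prominence=prominence)
    ref_density = traj.records[0].energy_z_density
    inner, flanks = energy_split(rec, necks.neck_positions, ref_density,
                                 rec.contour.z[1] - rec.contour.z[0])
    return CriticalState(time=rec.time, dF_e=rec.energy.F_e - Fe0, necks=necks,
                         inner=inner, flanks=flanks, record=rec)


def energy_split(record: TrajectoryRecord, neck_positions, ref_density: np.ndarray,
                 dz: float) -> tuple[float, float]:
    """Split the elastic energy excess between inner region and outer flanks.

    The excess linear density (relative to the unperturbed tubule) is
    integrated over z between the outermost necks ("inner") and outside
    them ("flanks"); inner + flanks equals the total dF_e to round-off.
    With fewer than two necks the inner region is empty by convention.
    """
    excess = (record.energy_z_density - ref_density) * dz
    if len(neck_positions) < 2:
        return 0.0, float(excess.sum())
    lo, hi = min(neck_positions), max(neck_positions)
    z = record.contour.z
    inside = (z >= lo) & (z <= hi)
    return float(excess[inside].sum()), float(excess[~inside].sum())


def conductance(contour: MidplaneContour, l_me: float = 5.0,
                lambda_D: float = 1.0) -> float:
    """Series-resistance lumenal conductance (arbitrary units of nm).

    The conducting lumen radius is the midplane radius minus half the
    bilayer thickness minus a Debye screening length,
    r_lum(z) = max(0, r_mid(z) - l_me/2 - lambda_D); the channel conducts
    as resistors in series, G = [integral dz / (pi r_lum^2)]^-1, and is 0
    as soon as any section closes.  Only the normalized trace G_n = G/G(0)
    is physically reported, so the overall conductivity factor is dropped.
    """
    if contour.any_closed:
        return 0.0
    r_lum = contour.r_mid - 0.5 * l_me - lambda_D
    if (r_lum <= 0.0).any():
        return 0.0
    dz = contour.z[1] - contour.z[0]
    resistance = float((dz / (math.pi * r_lum**2)).sum())
    return 1.0 / resistance


def conductance_trace(traj: Trajectory, l_me: float = 5.0,
                      lambda_D: float = 1.0) -> ConductanceTrace:
    """Normalized Debye-corrected conductance G_n(t) along a trajectory."""
    times = traj.times
    G = np.array([conductance(rec.contour, l_me, lambda_D) for rec in traj.records])
    G0 = G[0]
    if G0 <= 0:
        raise ValueError("initial state has no open lumen; cannot normalize")
    return ConductanceTrace(times=times, G_n=G / G0, lambda_D=lambda_D)


def trajectory_observables_frame(traj: Trajectory, coats=None, l_me: float = 5.0,
                                 lambda_D: float = 1.0):
    """Per-record observables table: radii, necks, energies, conductance.

    Columns: t_s, R_n_nm, R_c_nm, n_necks, D_nm, dFe_kBT, G_n, fission_flag.
    """
    import pandas as pd

    Fe0 = traj.records[0].energy.F_e
    G0 = conductance(traj.records[0].contour, l_me, lambda_D)
    rows = []
    for rec in traj.records:
        if rec.fission:
            necks = NeckAnalysis((), rec.R_n, rec.R_n, 0.0, 0)
        else:
            necks = analyze_necks(rec.contour, coats)
        G = conductance(rec.contour, l_me, lambda_D)
        rows.append({
            "t_s": rec.time,
            "R_n_nm": rec.R_n,
            "R_c_nm": necks.R_c,
            "n_necks": necks.n_necks,
            "D_nm": necks.D,
            "dFe_kBT": rec.energy.F_e - Fe0,
            "G_n": G / G0 if G0 > 0 else np.nan,
            "fission_flag": int(rec.fission),
        })
    return pd.DataFrame(rows)


def fission_time(traj: Trajectory, t_onset: float = 0.0) -> float:
    """Time from forcing onset to the first severed state (s)."""
    if traj.fission_time is None:
        raise ValueError("trajectory did not reach fission")
    return traj.fission_time - t_onset
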