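"""Synthetic fields, contours and trajectories for testing observables.

These generators build states with known ground truth — tubules whose
midplane radius profile r(z) is prescribed analytically — so that contour
extraction, neck analysis, conductance and critical-state logic can be
validated in isolation from the dynamics.
"""

from __future__ import annotations

import math

import numpy as np

from .dynamics import Trajectory, TrajectoryRecord
from .energetics import EnergyBreakdown
from .fields import AxisymmetricGrid, MidplaneContour

__all__ = [
    "cosine_radius_profile",
    "phase_field_from_profile",
    "contour_from_profile",
    "synthetic_trajectory",
]

_SQRT2 = math.sqrt(2.0)


def cosine_radius_profile(z: np.ndarray, R0: float, amplitude: float,
                          wavelength: float, phase: float = 0.0) -> np.ndarray:
    """r(z) = R0 - amplitude * cos(2 pi z / wavelength + phase): dimpled tubule."""
    return R0 - amplitude * np.cos(2.0 * np.pi * np.asarray(z) / wavelength + phase)


def phase_field_from_profile(grid: AxisymmetricGrid, r_mid: np.ndarray,
                             epsilon: float) -> np.ndarray:
    """tanh phase field whose phi = 0 level set follows the given r_mid(z).

    Columns with r_mid <= 0 are generated fully closed (phi = -1), which
    emulates a severed tubule.
    """
    r = grid.r_centers[:, None]
    prof = np.asarray(r_mid)[None, :]
    phi = np.tanh((prof - r) / (_SQRT2 * epsilon))
    phi = np.where(prof <= 0.0, -1.0, phi)
    return phi


def contour_from_profile(z: np.ndarray, r_mid: np.ndarray) -> MidplaneContour:
    """Wrap an analytic profile as a contour; r_mid <= 0 marks closed columns."""
    r_mid = np.asarray(r_mid, dtype=float).copy()
    closed = r_mid <= 0.0
    r_mid[closed] = np.nan
    return MidplaneContour(z=np.asarray(z, dtype=float), r_mid=r_mid, closed=closed)


def synthetic_trajectory(times: np.ndarray, elastic_energies: np.ndarray,
                         contours: list[MidplaneContour],
                         z_densities: list[np.ndarray] | None = None) -> Trajectory:
    """Assemble a trajectory from prescribed energies and contours.

    Fission events are inferred from closed contour columns, mirroring the
    bookkeeping of a real run; energy z-densities default to uniform
    profiles consistent with the prescribed totals.
    """
    times = np.asarray(times, dtype=float)
    energies = np.asarray(elastic_energies, dtype=float)
    if not (len(times) == len(energies) == len(contours)):
        raise ValueError("times, energies and contours must have equal length")
    traj = Trajectory()
    fission_seen = False
    for i, (t, Fe, cont) in enumerate(zip(times, energies, contours)):
        if z_densities is not None:
            e_z = np.asarray(z_densities[i], dtype=float)
        else:
            L = cont.z[-1] - cont.z[0] + (cont.z[1] - cont.z[0])
            e_z = np.full(cont.z.size, Fe / L)
        fission = cont.any_closed
        open_r = cont.r_mid[~cont.closed]
        R_n = float(np.nanmin(open_r)) if np.isfinite(open_r).any() else 0.0
        traj.records.append(TrajectoryRecord(
            time=float(t), energy=EnergyBreakdown(F_b=float(Fe), F_G=0.0, F_gamma=0.0),
            contour=cont, energy_z_density=e_z, R_n=R_n, fission=fission,
            residual=np.nan,
        ))
        if fission and not fission_seen:
            fission_seen = True
            traj.fission_time = float(t)
            closed_z = cont.z[cont.closed]
            traj.fission_z = float(closed_z.mean()) if closed_z.size else None
            traj.events.append((float(t), "fission"))
    traj.outcome = "fission" if fission_seen else "inconclusive"
    return traj
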