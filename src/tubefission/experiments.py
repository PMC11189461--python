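"""Orchestrated parameter sweeps and figure-level reproductions.

Coat-length sweeps (equilibrium vs critical radii, activation energy and
neck distance as functions of H), bisection for the neck-splitting
threshold H*, its comparison with the linearized-elasticity prediction,
and conductance traces for single- and multi-collar scenarios.  All runs
are deterministic; reduced-scale domains are configured through the base
:class:`~tubefission.config.RunConfig`.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .observables import analyze_necks, conductance_trace, critical_state
from .sharp import equilibrium_radius, linear_threshold

__all__ = [
    "SweepSpec",
    "ThresholdBracket",
    "run_single",
    "h_sweep",
    "find_threshold",
    "conductance_experiment",
]


@dataclass
class SweepSpec:
    """A sweep of one coat parameter over a base configuration."""

    base: RunConfig
    H_values: list[float] = field(default_factory=list)
    max_time: float | None = None


@dataclass
class ThresholdBracket:
    """Bracket [H_below, H_above] for the one-to-two-neck transition."""

    H_below: float
    H_above: float
    R_in: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.H_below + self.H_above)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.H_above - self.H_below)


def _config_with_H(base: RunConfig, H: float) -> RunConfig:
    cfg = copy.deepcopy(base)
    if not cfg.coats:
        cfg.coats = [{"H_nm": H, "center_nm": cfg.grid["L_z_nm"] / 2.0}]
    else:
        cfg.coats[0] = dict(cfg.coats[0], H_nm=H)
    return cfg


def run_single(cfg: RunConfig, max_time: float | None = None):
    """Run one configuration; returns (trajectory, simulation)."""
    sim = cfg.build_simulation()
    traj = sim.run(max_time=max_time if max_time is not None else cfg.max_time,
                   post_fission_time=cfg.post_fission_time)
    return traj, sim


def h_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Sweep the coat polymerization length H.

    Per H the summary records the outcome, the neck radius of the final
    (equilibrium) or critical state, the radius at the coat center, the
    activation energy dF_e, the number of critical necks and their
    distance D, and the fission time where fission occurs.  Individual run
    failures are logged in the ``error`` column and the sweep continues.
    """
    rows = []
    for H in spec.H_values:
        cfg = _config_with_H(spec.base, H)
        row: dict = {"H_nm": H}
        try:
            traj, sim = run_single(cfg, max_time=spec.max_time)
            row["outcome"] = traj.outcome
            row["fission"] = traj.outcome == "fission"
            Fe0 = traj.records[0].energy.F_e
            if traj.outcome == "fission":
                crit = critical_state(traj, sim.coats)
                row.update(
                    R_n_crit=crit.necks.R_n, R_c_crit=crit.necks.R_c,
                    dFe_crit=crit.dF_e, n_necks=crit.necks.n_necks,
                    D_nm=crit.necks.D, t_f_s=traj.fission_time,
                    dFe_inner=crit.inner, dFe_flanks=crit.flanks,
                    R_n_eq=0.0,
                )
            else:
                last = traj.records[-1]
                necks = analyze_necks(last.contour, sim.coats)
                row.update(
                    R_n_eq=necks.R_n, R_c_crit=necks.R_c,
                    dFe_crit=last.energy.F_e - Fe0,
                    n_necks=necks.n_necks, D_nm=necks.D,
                )
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad points
            row["outcome"] = "error"
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _critical_neck_count(base: RunConfig, H: float,
                         max_time: float | None) -> int:
    cfg = _config_with_H(base, H)
    traj, sim = run_single(cfg, max_time=max_time)
    crit = critical_state(traj, sim.coats)
    if crit is None:
        raise RuntimeError(f"no fission at H={H} nm: cannot classify the critical state")
    return crit.necks.n_necks


def find_threshold(base: RunConfig, H_lo: float, H_hi: float,
                   bracket_width: float = 5.0,
                   max_time: float | None = None) -> ThresholdBracket:
    """Bisect the neck-splitting threshold H* on the fission branch.

    ``H_lo`` must produce a single critical neck and ``H_hi`` two; the
    bracket is narrowed to ``bracket_width`` nm.  The necks of the critical
    state anticipate the fission sites, so this is also the single- vs
    two-site fission threshold.
    """
    params = base.build_elastic()
    R_in = base.R_in_nm or equilibrium_radius(params.k_b, params.gamma)
    n_lo = _critical_neck_count(base, H_lo, max_time)
    n_hi = _critical_neck_count(base, H_hi, max_time)
    if not (n_lo == 1 and n_hi >= 2):
        raise ValueError(
            f"bracket does not straddle the transition: n({H_lo})={n_lo}, "
            f"n({H_hi})={n_hi}; widen the initial interval"
        )
    while H_hi - H_lo > bracket_width:
        H_mid = 0.5 * (H_lo + H_hi)
        if _critical_neck_count(base, H_mid, max_time) == 1:
            H_lo = H_mid
        else:
            H_hi = H_mid
    return ThresholdBracket(H_below=H_lo, H_above=H_hi, R_in=R_in)


def compare_with_linear_threshold(bracket: ThresholdBracket) -> dict:
    """Summary of the nonlinear threshold against H*_l.e. = 2 sqrt(2) pi R_in."""
    H_le = linear_threshold(bracket.R_in)
    return {
        "R_in_nm": bracket.R_in,
        "H_star_nm": bracket.midpoint,
        "H_star_bracket_nm": (bracket.H_below, bracket.H_above),
        "H_star_le_nm": H_le,
        "nonlinear_below_linear": bracket.H_above < H_le,
    }


def conductance_experiment(cfg: RunConfig, l_me: float = 5.0,
                           lambda_D: float = 1.0,
                           max_time: float | None = None):
    """Run a (possibly multi-collar) configuration and return its G_n(t) trace."""
    traj, _sim = run_single(cfg, max_time=max_time)
    return conductance_trace(traj, l_me=l_me, lambda_D=lambda_D), traj
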