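"""Dynamin coat model: constriction pressure and its coupling to the membrane.

A dynamin helix of polymerization length H, pitch h and N_d dimers per turn
exerts ratchet-like tangential power strokes of magnitude F_tau between
dimers of adjacent rungs.  At the mesoscale this chain tension projects
onto the lipid tubule as an inward radial pressure

    p(r, z) = (N_d F_tau / (h r)) * A(z) * C(r),

where the 1/r law reflects the hoop tension of the chain, A(z) is an axial
envelope that is 1 on the coat interior and tapers smoothly to 0 over one
pitch at each end (tension builds up in the two extremal rungs and is
constant in the inner ones), and C(r) shuts the pressure off below the
maximum curvature the helix structure admits (tubule radius ~3 nm).

The pressure couples to the phase field through the mediating function
h(phi) = (3/4)(phi - phi^3/3), whose gradient-weighted profile converges
weakly to a surface delta on the midplane, so the interaction energy
I = integral(h(phi) p dV) spreads the sharp-interface pressure over the
diffuse interface.  On fission, dynamin depolymerizes and the pressure
vanishes without depositing energy on the membrane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KBT_PN_NM
from .fields import AxisymmetricGrid

__all__ = [
    "DynaminCoat",
    "CoatSet",
    "pressure_field",
    "mediating",
    "interaction_energy",
    "external_force_density",
    "depolymerize_on_fission",
]


@dataclass(frozen=True)
class DynaminCoat:
    """Geometry and force scale of one helical dynamin coat.

    Attributes
    ----------
    H:
        Polymerization length along the tubule axis (nm).
    z_0:
        Coat center (nm).
    F_tau:
        Tangential power-stroke force per dimer pair (pN).
    h_pitch:
        Helix pitch, i.e. axial rise per turn (nm).
    N_d:
        Dimers per turn.
    R_cut:
        Tubule radius below which the helix cannot constrict further and
        the pressure fades to zero (nm).
    cut_width:
        Width of the smooth radial cutoff ramp (nm).
    edge_width:
        Axial taper width at each coat end (nm); defaults to one pitch.
    active:
        Inactive coats exert no pressure (set after depolymerization).
    """

    H: float
    z_0: float
    F_tau: float = 2.5
    h_pitch: float = 10.0
    N_d: int = 13
    R_cut: float = 3.0
    cut_width: float = 0.5
    edge_width: float | None = None
    active: bool = True

    def __post_init__(self) -> None:
        if self.H <= 0:
            raise ValueError("polymerization length H must be positive")
        if self.edge_width is None:
            object.__setattr__(self, "edge_width", self.h_pitch)
        if self.H < self.h_pitch:
            warnings.warn(
                f"coat H={self.H} nm shorter than one pitch ({self.h_pitch} nm): the "
                "chain-tension pressure model assumes at least one full turn",
                stacklevel=2,
            )

    @property
    def plateau_pressure_coeff(self) -> float:
        """N_d F_tau / h in pN/nm: p(r) = coeff / r on the coat interior."""
        return self.N_d * self.F_tau / self.h_pitch

    def pressure_at(self, R: float) -> float:
        """Interior plateau pressure N_d F_tau/(h R) in pN/nm^2 (taper/cutoff off)."""
        return self.plateau_pressure_coeff / R

    def axial_envelope(self, z: np.ndarray) -> np.ndarray:
        """A(z): 1 on the coat interior, half-cosine ramps inside the ends.

        The support is exactly the coat extent [z_0 - H/2, z_0 + H/2]: the
        chain tension builds up across the two extremal rungs, so the
        pressure ramps from zero at each coat end to the interior plateau
        over ``edge_width`` (one pitch), shrunk to H/2 for sub-two-rung
        coats so that A(z_0) = 1 always.
        """
        dzc = np.abs(z - self.z_0)
        half = self.H / 2.0
        e = min(self.edge_width, half)
        A = np.zeros_like(dzc)
        A[dzc <= half - e] = 1.0
        ramp = (dzc > half - e) & (dzc < half)
        A[ramp] = 0.5 * (1.0 + np.cos(np.pi * (dzc[ramp] - (half - e)) / e))
        return A

    def radial_cutoff(self, r: np.ndarray) -> np.ndarray:
        """C(r): smooth tanh ramp, ->1 for r >> R_cut and ->0 for r <= R_cut."""
        return 0.5 * (1.0 + np.tanh((r - self.R_cut) / self.cut_width))

    def footprint(self) -> tuple[float, float]:
        """Axial support [z_min, z_max] of the pressure (= the coat extent)."""
        return self.z_0 - self.H / 2.0, self.z_0 + self.H / 2.0


@dataclass
class CoatSet:
    """A collection of dynamin coats acting on the same tubule."""

    coats: list[DynaminCoat] = field(default_factory=list)

    def __post_init__(self) -> None:
        spans = sorted(c.footprint() for c in self.coats if c.active)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                warnings.warn("dynamin coats overlap in z; pressures will add",
                              stacklevel=2)

    def __iter__(self):
        return iter(self.coats)

    def __len__(self) -> int:
        return len(self.coats)

    @property
    def active(self) -> list[DynaminCoat]:
        return [c for c in self.coats if c.active]


def _as_coatset(coats) -> CoatSet:
    if isinstance(coats, DynaminCoat):
        return CoatSet([coats])
    if isinstance(coats, CoatSet):
        return coats
    return CoatSet(list(coats))


def pressure_field(coats, grid: AxisymmetricGrid, check_domain: bool = True) -> np.ndarray:
    """Total dynamin pressure p(r, z) on the grid, in pN/nm^2.

    The pressure is evaluated on the Eulerian grid, independent of the phase
    field; it couples to the membrane only through the h(phi) spreading in
    the interaction energy.
    """
    coatset = _as_coatset(coats)
    r, z = grid.meshgrid()
    p = np.zeros(grid.shape)
    for coat in coatset.active:
        lo, hi = coat.footprint()
        if check_domain and (lo < 0.0 or hi > grid.L_z):
            raise ValueError(
                f"coat footprint [{lo:.1f}, {hi:.1f}] nm extends outside the "
                f"axial domain [0, {grid.L_z:.1f}] nm"
            )
        p += (coat.plateau_pressure_coeff / r) * coat.axial_envelope(z) * coat.radial_cutoff(r)
    return p


def mediating(phi: np.ndarray) -> np.ndarray:
    """h(phi) = (3/4)(phi - phi^3/3); h(+-1) = +-1/2, h(0) = 0."""
    return 0.75 * (phi - phi**3 / 3.0)


def interaction_energy(grid: AxisymmetricGrid, phi: np.ndarray, coats,
                       p: np.ndarray | None = None) -> float:
    """I[phi] = integral(h(phi) p dV) in k_BT (pressure converted from pN/nm^2)."""
    if p is None:
        p = pressure_field(coats, grid)
    return grid.integrate(mediating(phi) * p) / KBT_PN_NM


def interaction_derivative(phi: np.ndarray, p: np.ndarray) -> np.ndarray:
    """dI/dphi = (3/4)(1 - phi^2) p, in k_BT/nm^3 (p given in pN/nm^2)."""
    return 0.75 * (1.0 - phi**2) * p / KBT_PN_NM


def external_force_density(grid: AxisymmetricGrid, phi: np.ndarray, coats,
                           p: np.ndarray | None = None):
    """Spread force f_ext = (3/4)(1 - phi^2) p grad(phi), in pN/nm^3.

    Returns ``(f_r, f_z, dI_dphi)`` where ``dI_dphi`` (in k_BT/nm^3) is the
    scalar used directly by the Allen-Cahn dynamics.
    """
    if p is None:
        p = pressure_field(coats, grid)
    gr, gz = grid.gradient(phi)
    scal = 0.75 * (1.0 - phi**2) * p
    return scal * gr, scal * gz, scal / KBT_PN_NM


def depolymerize_on_fission(coats, fission: bool,
                            fission_z: float | None = None) -> CoatSet:
    """Deactivate coats overlapping a fission site.

    Dynamin polymers disassemble once the tubule is severed; their pressure
    field vanishes and no depolymerization energy enters the membrane.  If
    ``fission_z`` is None all active coats are deactivated.
    """
    coatset = _as_coatset(coats)
    if not fission:
        return coatset
    new = []
    for c in coatset:
        lo, hi = c.footprint()
        hit = fission_z is None or (lo <= fission_z <= hi)
        new.append(replace(c, active=False) if (c.active and hit) else c)
    return CoatSet(new)
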