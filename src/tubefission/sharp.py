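"""Sharp-interface and linearized-elasticity theory of the coated tubule.

Closed-form companions to the phase-field simulation:

* equilibrium tubule radius R_in = sqrt(k_b/(2 gamma)) and its constricted
  counterpart R_c = sqrt(k_b/(2 gamma_bar)) under the modified tension
  gamma_bar = gamma + N_d F_tau / h that a long dynamin coat imposes;
* the cylindrical-patch Hamiltonian k_b pi L / R + 2 pi gamma_bar R L;
* the fission-time estimate for long coats,
  t_f = alpha(F_tau) R_in^2 (gamma + gamma_bar) / (2 M_sharp gamma_bar^2);
* the linear response of a nearly cylindrical tubule,
  R_in^4 u'''' + u = p_bar R_in^4 / k_b, its exponentially damped
  oscillatory Green's function (decay length sqrt(2) R_in) and the
  neck-splitting threshold H*_l.e. = 2 sqrt(2) pi R_in;
* a residual evaluator for the full axisymmetric shape equation, used as a
  verification instrument for equilibrium profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft

from .constants import force_pn_to_kbt_per_nm
from .forcing import DynaminCoat

__all__ = [
    "SharpPrediction",
    "equilibrium_radius",
    "modified_tension",
    "constricted_radius",
    "cylinder_hamiltonian",
    "alpha_correction",
    "fission_time_prediction",
    "mobility_sharp",
    "greens_function",
    "linear_deformation",
    "linear_threshold",
    "count_linear_minima",
    "shape_equation_residual",
]

_SQRT2 = math.sqrt(2.0)


def equilibrium_radius(k_b: float, gamma: float) -> float:
    """Equilibrium tubule radius R_in = sqrt(k_b / (2 gamma)) in nm.

    ``k_b`` in k_BT, ``gamma`` in k_BT/nm^2 (use
    :func:`tubefission.constants.tension_si_to_kbt` for N/m inputs).
    """
    if k_b <= 0 or gamma <= 0:
        raise ValueError("k_b and gamma must be positive")
    return math.sqrt(k_b / (2.0 * gamma))


def modified_tension(gamma: float, coat: DynaminCoat) -> float:
    """gamma_bar = gamma + N_d F_tau / h, in k_BT/nm^2."""
    return gamma + force_pn_to_kbt_per_nm(coat.N_d * coat.F_tau) / coat.h_pitch


def constricted_radius(k_b: float, gamma_bar: float) -> float:
    """R_c = sqrt(k_b / (2 gamma_bar)): equilibrium radius under the coat."""
    return equilibrium_radius(k_b, gamma_bar)


def cylinder_hamiltonian(R: float, L: float, k_b: float, gamma_bar: float) -> float:
    """Energy of a cylindrical patch: k_b pi L / R + 2 pi gamma_bar R L (k_BT)."""
    if R <= 0 or L <= 0:
        raise ValueError("R and L must be positive")
    return k_b * math.pi * L / R + 2.0 * math.pi * gamma_bar * R * L


def mobility_sharp(M_pf: float, epsilon: float) -> float:
    """Sharp-interface mobility M_sharp = 3 eps M_pf / sqrt(8), nm^4/(s k_BT)."""
    if M_pf < 0 or epsilon <= 0:
        raise ValueError("M_pf must be >= 0 and epsilon > 0")
    return 3.0 * epsilon * M_pf / math.sqrt(8.0)


def alpha_correction(F_tau: float) -> float:
    """alpha(F_tau) = 1 + exp[(2.318 pN - F_tau)/0.805 pN], fitted on simulations."""
    return 1.0 + math.exp((2.318 - F_tau) / 0.805)


def fission_time_prediction(k_b: float, gamma: float, coat: DynaminCoat,
                            M_sharp: float) -> float:
    """Fission time t_f in seconds for a long coat (H above the splitting threshold).

    t_f = alpha(F_tau) * R_in^2/(2 M_sharp) * (gamma + gamma_bar)/gamma_bar^2.
    """
    R_in = equilibrium_radius(k_b, gamma)
    if coat.H < linear_threshold(R_in) / _SQRT2 / math.pi:  # below ~2 R_in: clearly short
        warnings.warn("fission-time formula derived for long coats; H is short",
                      stacklevel=2)
    gbar = modified_tension(gamma, coat)
    return alpha_correction(coat.F_tau) * R_in**2 / (2.0 * M_sharp) * (gamma + gbar) / gbar**2


def greens_function(z: np.ndarray | float, R_in: float) -> np.ndarray:
    """Green's function of R_in^4 u'''' + u = delta(z), decaying as exp(-|z|/(sqrt2 R_in)).

    g(z) = sqrt(2)/(4 R_in) exp(-|z|/a) (cos(|z|/a) + sin(|z|/a)), a = sqrt(2) R_in.
    """
    if R_in <= 0:
        raise ValueError("R_in must be positive")
    a = _SQRT2 * R_in
    x = np.abs(np.asarray(z, dtype=float)) / a
    return _SQRT2 / (4.0 * R_in) * np.exp(-x) * (np.cos(x) + np.sin(x))


def _greens_cumulative(x: np.ndarray, R_in: float) -> np.ndarray:
    """W(x) = integral of g from 0 to x; odd, W(+-inf) = +-1/2."""
    a = _SQRT2 * R_in
    t = np.abs(x) / a
    return np.sign(x) * 0.5 * (1.0 - np.exp(-t) * np.cos(t))


def linear_deformation(H: float, R_in: float, k_b: float, z: np.ndarray,
                       p_amplitude: float | None = None) -> np.ndarray:
    """Linear-response deformation u(z) under a rectangular pressure window.

    Solves R_in^4 u'''' + u = p_bar R_in^4 / k_b with
    p_bar(z) = -(k_b / R_in^4) * Pi(z/H) via the closed-form antiderivative of
    the Green's function:  u(z) = -(W(z + H/2) - W(z - H/2)).  A nonzero
    ``p_amplitude`` (k_BT/nm^3) rescales the unit-intensity window.
    """
    z = np.asarray(z, dtype=float)
    span = z.max() - z.min()
    if span < H + 10.0 * _SQRT2 * R_in:
        raise ValueError(
            "z grid must extend at least 10 decay lengths beyond the pressure window"
        )
    u = -(_greens_cumulative(z + H / 2.0, R_in) - _greens_cumulative(z - H / 2.0, R_in))
    if p_amplitude is not None:
        u *= p_amplitude * R_in**4 / k_b
    return u


def linear_threshold(R_in: float) -> float:
    """H*_l.e. = 2 sqrt(2) pi R_in: coat length where the single dimple splits."""
    if R_in <= 0:
        raise ValueError("R_in must be positive")
    return 2.0 * _SQRT2 * math.pi * R_in


def count_linear_minima(u: np.ndarray, rel_depth_tol: float = 1e-3) -> int:
    """Count the maximum-constriction sites of a sampled deformation profile.

    The damped-oscillatory Green's function gives u(z) infinitely many
    shallow stationary points; the necks are the strict local minima whose
    depth is within ``rel_depth_tol`` (relative) of the global minimum.
    Below the splitting threshold there is a single such site at the window
    center; above it, two symmetric sites near the window edges.
    """
    u = np.asarray(u, dtype=float)
    u_min = u.min()
    if u_min >= 0.0:
        return 0
    interior = u[1:-1]
    is_min = (interior < u[:-2]) & (interior <= u[2:])
    deep = interior <= u_min + rel_depth_tol * abs(u_min)
    return int((is_min & deep).sum())


@dataclass(frozen=True)
class SharpPrediction:
    """Bundle of analytic predictions for one (membrane, coat) configuration."""

    R_in: float
    gamma_bar: float
    R_c: float
    H_star_le: float
    L_dec: float
    M_sharp: float
    alpha: float
    t_f: float

    @classmethod
    def from_parameters(cls, k_b: float, gamma: float, coat: DynaminCoat,
                        M_pf: float = 4.04, epsilon: float = 5.0 / 6.0) -> "SharpPrediction":
        R_in = equilibrium_radius(k_b, gamma)
        gbar = modified_tension(gamma, coat)
        M_sh = mobility_sharp(M_pf, epsilon)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_f = fission_time_prediction(k_b, gamma, coat, M_sh)
        return cls(
            R_in=R_in,
            gamma_bar=gbar,
            R_c=constricted_radius(k_b, gbar),
            H_star_le=linear_threshold(R_in),
            L_dec=_SQRT2 * R_in,
            M_sharp=M_sh,
            alpha=alpha_correction(coat.F_tau),
            t_f=t_f,
        )

    def as_dict(self) -> dict:
        return {
            "R_in_nm": self.R_in,
            "gamma_bar_kbt_nm2": self.gamma_bar,
            "R_c_nm": self.R_c,
            "H_star_le_nm": self.H_star_le,
            "L_dec_nm": self.L_dec,
            "M_sharp_nm4_s_kbt": self.M_sharp,
            "alpha": self.alpha,
            "t_f_s": self.t_f,
        }


def shape_equation_residual(z: np.ndarray, r_profile: np.ndarray,
                            psi_profile: np.ndarray, p_profile: np.ndarray,
                            k_b: float, gamma: float) -> np.ndarray:
    """Residual of the axisymmetric Canham-Helfrich shape equation.

    The midplane is parametrized by the distance r(z) from the symmetry
    axis and the angle psi(z) between the r-axis and the profile tangent
    (psi = pi/2 for a perfect cylinder).  With s = sin(psi), c = cos(psi)
    the stationarity condition reads

        2 r^2 s^3 psi''' + 8 r^2 s^2 c psi'' psi' + r s (2 c^2 - s^2) psi'^3
        + 4 r c s^2 psi'' + r s (4 - 7 s^2) psi'^2 - (3 c^2 - 1) s psi'
        - 2 r^2 s psi' gamma/k_b - 2 r s gamma/k_b + (1 + c^2) s / r
        = -2 r^2 p / k_b,

    and the returned field is LHS - RHS (zero for an equilibrium profile).
    Derivatives of psi are spectral, so profiles must be periodic on ``z``.
    This is a verification instrument; the phase field is the nonlinear
    solver.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    dz = z[1] - z[0]
    k = 2.0 * np.pi * sfft.rfftfreq(n, dz)
    psihat = sfft.rfft(psi_profile)
    d1 = sfft.irfft(1j * k * psihat, n=n)
    d2 = sfft.irfft(-(k**2) * psihat, n=n)
    d3 = sfft.irfft(-1j * k**3 * psihat, n=n)
    r = r_profile
    s = np.sin(psi_profile)
    c = np.cos(psi_profile)
    gk = gamma / k_b
    lhs = (
        2.0 * r**2 * s**3 * d3
        + 8.0 * r**2 * s**2 * c * d2 * d1
        + r * s * (2.0 * c**2 - s**2) * d1**3
        + 4.0 * r * c * s**2 * d2
        + r * s * (4.0 - 7.0 * s**2) * d1**2
        - (3.0 * c**2 - 1.0) * s * d1
        - 2.0 * r**2 * s * d1 * gk
        - 2.0 * r * s * gk
        + (1.0 + c**2) / r * s
    )
    rhs = -2.0 * r**2 * p_profile / k_b
    return lhs - rhs
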