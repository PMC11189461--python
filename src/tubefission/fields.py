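"""Axisymmetric computational domain, spectral operators and contours.

The membrane phase field lives on a homogeneous, cell-centered (r, z)
lattice.  Differentiation is Fourier-spectral in both directions:

* the axial direction is periodic, so plain FFTs apply;
* the radial direction is handled by mirror extension across the symmetry
  axis (even for scalars, odd for radial vector components), which turns
  the half-domain [0, L_r] into a 2*L_r-periodic problem.  The cell-centered
  lattice never samples r = 0, so the 1/r metric terms stay finite.

The outer radial boundary therefore carries an even (zero normal
derivative) extension; fields must relax to their bulk value (phi = -1)
well before r = L_r, which callers are expected to check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft as sfft

__all__ = [
    "AxisymmetricGrid",
    "MidplaneContour",
    "extract_midplane_contour",
]


@dataclass(frozen=True)
class AxisymmetricGrid:
    """Homogeneous cell-centered lattice on [0, L_r] x [0, L_z).

    Parameters
    ----------
    L_r, L_z:
        Radial and axial extents in nm.  The axial direction is periodic.
    N_r, N_z:
        Number of cells in each direction.

    Cell centers sit at ``r_j = (j + 1/2) dr`` and ``z_i = i dz``; the grid
    never touches the symmetry axis, which is how the coordinate
    singularity of the cylindrical Laplacian is avoided.
    """

    L_r: float
    L_z: float
    N_r: int
    N_z: int

    def __post_init__(self) -> None:
        if self.L_r <= 0 or self.L_z <= 0:
            raise ValueError("domain extents must be positive")
        if self.N_r < 8 or self.N_z < 8:
            raise ValueError("grid too coarse: need at least 8 cells per direction")

    # -- geometry ---------------------------------------------------------
    @property
    def dr(self) -> float:
        return self.L_r / self.N_r

    @property
    def dz(self) -> float:
        return self.L_z / self.N_z

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.N_r) + 0.5) * self.dr

    @property
    def z_centers(self) -> np.ndarray:
        return np.arange(self.N_z) * self.dz

    @property
    def shape(self) -> tuple[int, int]:
        return (self.N_r, self.N_z)

    def validate_resolution(self, epsilon: float) -> None:
        """Reject grids that cannot resolve a diffuse interface of width epsilon."""
        if self.dr > epsilon / 2 + 1e-12 or self.dz > epsilon / 2 + 1e-12:
            raise ValueError(
                f"grid spacing (dr={self.dr:.3g}, dz={self.dz:.3g}) exceeds "
                f"epsilon/2={epsilon / 2:.3g}; the interface would be unresolved"
            )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcastable (r, z) coordinate arrays of shape (N_r, 1), (1, N_z)."""
        return self.r_centers[:, None], self.z_centers[None, :]

    # -- spectral machinery ----------------------------------------------
    @property
    def _kr(self) -> np.ndarray:
        # wavenumbers of the 2*L_r-periodic mirror extension
        return 2.0 * np.pi * sfft.fftfreq(2 * self.N_r, self.dr)[:, None]

    @property
    def _kz(self) -> np.ndarray:
        return 2.0 * np.pi * sfft.rfftfreq(self.N_z, self.dz)[None, :]

    def _check(self, f: np.ndarray) -> None:
        if f.shape != self.shape:
            raise ValueError(f"field shape {f.shape} does not match grid {self.shape}")

    def _ext(self, f: np.ndarray, parity: int = +1) -> np.ndarray:
        """Mirror-extend across the axis: even (+1) or odd (-1)."""
        return np.concatenate([parity * f[::-1, :], f], axis=0)

    def fwd(self, f: np.ndarray, parity: int = +1) -> np.ndarray:
        """Forward transform of the mirror-extended field."""
        return sfft.rfft2(self._ext(f, parity))

    def inv(self, fhat: np.ndarray) -> np.ndarray:
        """Inverse transform, restricted to the physical half-domain."""
        return sfft.irfft2(fhat, s=(2 * self.N_r, self.N_z))[self.N_r:, :]

    # -- differential operators ------------------------------------------
    def d_dr(self, f: np.ndarray, parity: int = +1) -> np.ndarray:
        """Radial derivative of a field with the given mirror parity."""
        self._check(f)
        return self.inv(1j * self._kr * self.fwd(f, parity))

    def d_dz(self, f: np.ndarray, parity: int = +1) -> np.ndarray:
        """Axial derivative (periodic)."""
        self._check(f)
        return self.inv(1j * self._kz * self.fwd(f, parity))

    def gradient(self, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(df/dr, df/dz) of an even scalar field."""
        self._check(f)
        fhat = self.fwd(f)
        return self.inv(1j * self._kr * fhat), self.inv(1j * self._kz * fhat)

    def laplacian(self, f: np.ndarray) -> np.ndarray:
        """Axisymmetric 3D Laplacian d2/dr2 + (1/r) d/dr + d2/dz2."""
        self._check(f)
        fhat = self.fwd(f)
        k2 = self._kr**2 + self._kz**2
        fr = self.inv(1j * self._kr * fhat)
        return self.inv(-k2 * fhat) + fr / self.r_centers[:, None]

    def divergence(self, vr: np.ndarray, vz: np.ndarray) -> np.ndarray:
        """Axisymmetric divergence (1/r) d(r vr)/dr + d vz/dz.

        The radial component of an axisymmetric vector field is odd across
        the axis and is extended accordingly.
        """
        self._check(vr)
        self._check(vz)
        vrhat = self.fwd(vr, parity=-1)
        vzhat = self.fwd(vz)
        out = self.inv(1j * self._kr * vrhat + 1j * self._kz * vzhat)
        out += vr / self.r_centers[:, None]
        return out

    # -- integrals --------------------------------------------------------
    def integrate(self, f: np.ndarray) -> float:
        """Volume integral sum(f * 2 pi r dr dz); exact for cellwise-constant f."""
        self._check(f)
        return float(2.0 * np.pi * self.dr * self.dz * (f * self.r_centers[:, None]).sum())

    def integrate_z_density(self, f: np.ndarray) -> np.ndarray:
        """Linear (per-unit-length) density: integral of f over 2 pi r dr, per z column."""
        self._check(f)
        return 2.0 * np.pi * self.dr * (f * self.r_centers[:, None]).sum(axis=0)


@dataclass
class MidplaneContour:
    """Midplane radius r(z) of the phi = 0 level set.

    ``closed`` marks z columns with no sign change (phi < 0 for every r),
    i.e. columns where the tubule lumen has been severed; ``r_mid`` is NaN
    there.
    """

    z: np.ndarray
    r_mid: np.ndarray
    closed: np.ndarray
    multiple_crossings: bool = field(default=False)

    @property
    def any_closed(self) -> bool:
        return bool(self.closed.any())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"z_nm": self.z, "r_mid_nm": self.r_mid, "closed_flag": self.closed.astype(int)}
        )


def extract_midplane_contour(grid: AxisymmetricGrid, phi: np.ndarray) -> MidplaneContour:
    """Locate the outermost phi = 0 crossing in every z column.

    The crossing is found by linear interpolation between adjacent cell
    centers.  Where several crossings exist (e.g. transient satellite
    droplets) the outermost one is taken as the membrane midplane and the
    contour is flagged.  Columns with phi < 0 everywhere are marked closed.
    """
    grid._check(phi)
    r = grid.r_centers
    N_r, N_z = grid.shape
    sign = phi > 0.0
    r_mid = np.full(N_z, np.nan)
    closed = np.zeros(N_z, dtype=bool)
    multi = False
    for i in range(N_z):
        col = phi[:, i]
        pos = sign[:, i]
        if not pos.any():
            closed[i] = True
            continue
        # indices j with a sign change between cells j and j+1
        flips = np.nonzero(pos[:-1] != pos[1:])[0]
        if flips.size == 0:
            # positive everywhere: interface pushed outside the domain
            r_mid[i] = r[-1]
            continue
        if flips.size > 1:
            multi = True
        j = flips[-1]  # outermost crossing
        f0, f1 = col[j], col[j + 1]
        r_mid[i] = r[j] + (r[j + 1] - r[j]) * f0 / (f0 - f1)
    return MidplaneContour(z=grid.z_centers.copy(), r_mid=r_mid, closed=closed,
                           multiple_crossings=multi)
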