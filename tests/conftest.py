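"""Shared fixtures: parameter sets, small grids and reference states.

Heavy simulation fixtures (reduced-scale fission runs) are session-scoped
and shared between the dynamics, observables and acceptance tests so each
run happens once per session.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from tubefission.dynamics import Simulation, TimeStepper
from tubefission.energetics import ElasticParameters
from tubefission.fields import AxisymmetricGrid
from tubefission.forcing import DynaminCoat

SQRT2 = math.sqrt(2.0)

np.seterr(over="ignore", invalid="ignore")  # rejected diverging inner iterates


@pytest.fixture(scope="session")
def params() -> ElasticParameters:
    """Default membrane parameters: k_b=20 k_BT, k_G=-k_b, gamma=1.5e-4 N/m."""
    return ElasticParameters()


@pytest.fixture(scope="session")
def small_grid() -> AxisymmetricGrid:
    """Coarse but interface-resolving grid for cheap operator tests."""
    return AxisymmetricGrid(L_r=30.0, L_z=60.0, N_r=108, N_z=216)


@pytest.fixture(scope="session")
def cylinder_grid() -> AxisymmetricGrid:
    """Paper-spacing grid long enough for clean cylinder energies."""
    return AxisymmetricGrid(L_r=30.0, L_z=120.0, N_r=108, N_z=432)


def tanh_cylinder(grid: AxisymmetricGrid, R: float, epsilon: float) -> np.ndarray:
    r = grid.r_centers[:, None]
    return np.tanh((R - r) / (SQRT2 * epsilon)) * np.ones((1, grid.N_z))


def tanh_sphere(grid: AxisymmetricGrid, R: float, z_c: float, epsilon: float) -> np.ndarray:
    r, z = grid.meshgrid()
    rho = np.sqrt(r**2 + (z - z_c) ** 2)
    return np.tanh((R - rho) / (SQRT2 * epsilon))


@pytest.fixture(scope="session")
def tubule(cylinder_grid, params) -> np.ndarray:
    return tanh_cylinder(cylinder_grid, 16.6, params.epsilon)


def reduced_scale_sim(H: float, dphi_target: float = 0.01) -> Simulation:
    """Reduced-scale study configuration: 30 x 360 nm domain at paper spacing."""
    grid = AxisymmetricGrid(L_r=30.0, L_z=360.0, N_r=108, N_z=1296)
    coat = DynaminCoat(H=H, z_0=180.0)
    return Simulation(grid, ElasticParameters(), coats=[coat],
                      stepper=TimeStepper(record_every=10, dphi_target=dphi_target))


@pytest.fixture(scope="session")
def h20_run():
    """H = 20 nm coat at default parameters, run to fission (shared, ~5 min)."""
    sim = reduced_scale_sim(20.0)
    traj = sim.run(post_fission_time=0.2)
    return traj, sim


@pytest.fixture(scope="session")
def h35_run():
    """H = 35 nm coat: just below the neck-splitting threshold (~3 min).

    The neck-count classification is insensitive to the step-accuracy
    target, so this run uses the coarser 0.02 setting for speed.
    """
    sim = reduced_scale_sim(35.0, dphi_target=0.02)
    traj = sim.run(post_fission_time=0.05)
    return traj, sim


@pytest.fixture(scope="session")
def h45_run():
    """H = 45 nm coat: just above the neck-splitting threshold (~4 min)."""
    sim = reduced_scale_sim(45.0, dphi_target=0.02)
    traj = sim.run(post_fission_time=0.05)
    return traj, sim
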