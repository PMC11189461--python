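"""Neck analysis, fission detection, critical state, energy split, conductance."""

import math

import numpy as np
import pytest

from tubefission.energetics import ElasticParameters
from tubefission.fields import AxisymmetricGrid
from tubefission.forcing import DynaminCoat
from tubefission.observables import (
    analyze_necks,
    conductance,
    conductance_trace,
    critical_state,
    detect_fission,
    fission_time,
)
from tubefission.synthetic import (
    contour_from_profile,
    cosine_radius_profile,
    phase_field_from_profile,
    synthetic_trajectory,
)

SQRT2 = math.sqrt(2.0)


@pytest.fixture()
def z200():
    return np.arange(0.0, 200.0, 0.5)


class TestNeckAnalysis:
    def test_perfect_cylinder_has_no_neck(self, z200):
        cont = contour_from_profile(z200, np.full(z200.size, 10.0))
        res = analyze_necks(cont)
        assert res.n_necks == 0
        assert res.R_n == pytest.approx(10.0)
        assert res.R_c == pytest.approx(10.0)
        assert res.D == 0.0

    def test_single_cosine_dimple(self, z200):
        """r(z) = 10 - 3 cos(2 pi (z-100)/200): one neck at center, R_n = 7."""
        prof = cosine_radius_profile(z200, 10.0, 3.0, 200.0, phase=-np.pi)
        cont = contour_from_profile(z200, prof)
        coat = DynaminCoat(H=40.0, z_0=100.0)
        res = analyze_necks(cont, coat)
        assert res.n_necks == 1
        assert res.R_n == pytest.approx(7.0, abs=1e-3)
        assert res.neck_positions[0] == pytest.approx(100.0, abs=0.5)
        assert res.D == 0.0

    def test_two_dimples_with_center_plateau(self, z200):
        """Two symmetric necks flanking a constricted middle: D > 0, R_c > R_n."""
        d = np.abs(z200 - 100.0)
        # smooth walls rising to 12 outside, inner plateau at 8, dimples to ~7 at d=40
        prof = 8.0 + 4.0 / (1.0 + np.exp(-(d - 45.0) / 5.0)) \
            - 2.0 * np.exp(-((d - 40.0) ** 2) / 18.0)
        cont = contour_from_profile(z200, prof)
        res = analyze_necks(cont, DynaminCoat(H=100.0, z_0=100.0))
        assert res.n_necks == 2
        assert res.D == pytest.approx(80.0, abs=2.0)
        assert res.R_c > res.R_n

    def test_grid_scale_ripples_suppressed(self, z200):
        """Sub-threshold ripples (well below the 0.5 nm prominence) are no necks."""
        rng = np.random.default_rng(0)
        prof = 10.0 + 0.05 * rng.standard_normal(z200.size)
        cont = contour_from_profile(z200, prof)
        assert analyze_necks(cont).n_necks == 0

    def test_closed_contour_rejected(self, z200):
        prof = np.full(z200.size, 10.0)
        prof[100:110] = -1.0
        cont = contour_from_profile(z200, prof)
        with pytest.raises(ValueError, match="severed"):
            analyze_necks(cont)


class TestFissionDetection:
    def test_intact_tubule_not_severed(self, params):
        grid = AxisymmetricGrid(30.0, 60.0, 108, 216)
        prof = np.full(grid.N_z, 16.6)
        phi = phase_field_from_profile(grid, prof, params.epsilon)
        flag, z_f = detect_fission(grid, phi)
        assert not flag and z_f is None

    def test_forced_band_detected_at_center(self, params):
        grid = AxisymmetricGrid(30.0, 60.0, 108, 216)
        prof = np.full(grid.N_z, 16.6)
        band = slice(100, 110)
        prof[band] = -1.0
        phi = phase_field_from_profile(grid, prof, params.epsilon)
        flag, z_f = detect_fission(grid, phi)
        assert flag
        expected = grid.z_centers[band].mean()
        assert z_f == pytest.approx(expected, abs=grid.dz)


class TestCriticalState:
    def _traj(self, z, energies, profiles):
        conts = [contour_from_profile(z, p) for p in profiles]
        times = np.arange(len(energies), dtype=float)
        return synthetic_trajectory(times, energies, conts)

    def test_no_fission_means_no_critical_state(self, z200):
        profiles = [np.full(z200.size, 10.0)] * 3
        traj = self._traj(z200, [0.0, 1.0, 2.0], profiles)
        assert traj.outcome != "fission"
        assert critical_state(traj) is None

    def test_max_energy_state_selected(self, z200):
        dip = cosine_radius_profile(z200, 10.0, 4.0, 200.0, phase=-np.pi)
        severed = dip.copy()
        severed[195:205] = -1.0
        profiles = [np.full(z200.size, 10.0), dip, dip, severed]
        traj = self._traj(z200, [100.0, 180.0, 150.0, 40.0], profiles)
        crit = critical_state(traj)
        assert crit is not None
        assert crit.time == 1.0
        assert crit.dF_e == pytest.approx(80.0)

    def test_monotone_energy_picks_last_pre_fission_state(self, z200):
        dip = cosine_radius_profile(z200, 10.0, 4.0, 200.0, phase=-np.pi)
        severed = dip.copy()
        severed[195:205] = -1.0
        profiles = [np.full(z200.size, 10.0), dip, severed]
        traj = self._traj(z200, [0.0, 50.0, 10.0], profiles)
        crit = critical_state(traj)
        assert crit.time == 1.0


class TestEnergySplit:
    def test_single_neck_puts_everything_in_flanks(self, z200):
        dip = cosine_radius_profile(z200, 10.0, 3.0, 200.0, phase=-np.pi)
        severed = dip.copy()
        severed[100:104] = -1.0
        profiles = [np.full(z200.size, 10.0), dip, severed]
        traj = synthetic_trajectory([0.0, 1.0, 2.0], [10.0, 50.0, 5.0],
                                    [contour_from_profile(z200, p) for p in profiles])
        crit = critical_state(traj, DynaminCoat(H=40.0, z_0=100.0))
        assert crit.necks.n_necks == 1
        assert crit.inner == 0.0
        assert crit.flanks == pytest.approx(crit.dF_e)

    def test_two_neck_split_conserves_total(self, z200):
        d = np.abs(z200 - 100.0)
        prof = 8.0 + 4.0 / (1.0 + np.exp(-(d - 45.0) / 5.0)) \
            - 2.0 * np.exp(-((d - 40.0) ** 2) / 18.0)
        severed = prof.copy()
        severed[118:124] = -1.0
        base = np.full(z200.size, 12.0)
        # nonuniform energy density concentrated around the coat
        dens = [np.ones(z200.size), 1.0 + np.exp(-((z200 - 100.0) ** 2) / 500.0),
                np.ones(z200.size)]
        traj = synthetic_trajectory(
            [0.0, 1.0, 2.0],
            [d.sum() * 0.5 for d in dens],
            [contour_from_profile(z200, p) for p in (base, prof, severed)],
            z_densities=dens)
        crit = critical_state(traj, DynaminCoat(H=100.0, z_0=100.0))
        assert crit.necks.n_necks == 2
        assert crit.inner > 0.0
        assert crit.inner + crit.flanks == pytest.approx(crit.dF_e, rel=1e-12)


class TestConductance:
    def test_uniform_cylinder_normalizes_to_one(self, z200):
        cont = contour_from_profile(z200, np.full(z200.size, 10.0))
        traj = synthetic_trajectory([0.0], [0.0], [cont])
        trace = conductance_trace(traj)
        assert trace.G_n[0] == pytest.approx(1.0)

    def test_any_closed_column_gives_zero(self, z200):
        prof = np.full(z200.size, 10.0)
        prof[200] = -1.0
        cont = contour_from_profile(z200, prof)
        assert conductance(cont) == 0.0

    def test_lumen_below_screening_radius_gives_zero(self, z200):
        """Midplane open but lumen (r - l_me/2 - lambda_D) closed somewhere."""
        prof = np.full(z200.size, 10.0)
        prof[150] = 3.2  # lumen radius 3.2 - 2.5 - 1.0 < 0
        cont = contour_from_profile(z200, prof)
        assert conductance(cont, l_me=5.0, lambda_D=1.0) == 0.0

    def test_narrowing_any_section_decreases_conductance(self, z200):
        base = np.full(z200.size, 10.0)
        G0 = conductance(contour_from_profile(z200, base))
        rng = np.random.default_rng(1)
        for _ in range(5):
            prof = base.copy()
            prof[rng.integers(0, z200.size)] = 8.0
            assert conductance(contour_from_profile(z200, prof)) < G0


class TestObservablesFrame:
    def test_columns_and_normalization(self, z200):
        from tubefission.observables import trajectory_observables_frame

        base = np.full(z200.size, 10.0)
        dip = cosine_radius_profile(z200, 10.0, 3.0, 200.0, phase=-np.pi)
        severed = dip.copy()
        severed[100:104] = -1.0
        conts = [contour_from_profile(z200, p) for p in (base, dip, severed)]
        traj = synthetic_trajectory([0.0, 1.0, 2.0], [5.0, 50.0, 10.0], conts)
        df = trajectory_observables_frame(traj)
        assert list(df.columns) == ["t_s", "R_n_nm", "R_c_nm", "n_necks", "D_nm",
                                    "dFe_kBT", "G_n", "fission_flag"]
        assert df.loc[0, "G_n"] == pytest.approx(1.0)
        assert df.loc[2, "G_n"] == 0.0
        assert df.loc[2, "fission_flag"] == 1
        assert df.loc[1, "dFe_kBT"] == pytest.approx(45.0)


class TestFissionTime:
    def test_time_of_first_severed_record(self, z200):
        base = np.full(z200.size, 10.0)
        severed = base.copy()
        severed[100:105] = -1.0
        conts = [contour_from_profile(z200, p) for p in (base, base, severed, severed)]
        traj = synthetic_trajectory([0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 0.5, 0.2], conts)
        assert fission_time(traj) == pytest.approx(2.0)
        assert fission_time(traj, t_onset=0.5) == pytest.approx(1.5)

    def test_no_fission_raises(self, z200):
        cont = contour_from_profile(z200, np.full(z200.size, 10.0))
        traj = synthetic_trajectory([0.0], [0.0], [cont])
        with pytest.raises(ValueError):
            fission_time(traj)
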