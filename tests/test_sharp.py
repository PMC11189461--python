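"""Sharp-interface closed forms and the linearized tubule response."""

import math
import warnings

import numpy as np
import pytest
import scipy.fft as sfft
from hypothesis import given, settings
from hypothesis import strategies as st

from tubefission.constants import tension_si_to_kbt
from tubefission.forcing import DynaminCoat
from tubefission.sharp import (
    SharpPrediction,
    alpha_correction,
    constricted_radius,
    count_linear_minima,
    cylinder_hamiltonian,
    equilibrium_radius,
    fission_time_prediction,
    greens_function,
    linear_deformation,
    linear_threshold,
    mobility_sharp,
    modified_tension,
    shape_equation_residual,
)

SQRT2 = math.sqrt(2.0)


class TestEquilibriumRadii:
    def test_printed_radius_at_default_parameters(self):
        R = equilibrium_radius(20.0, tension_si_to_kbt(1.5e-4))
        assert R == pytest.approx(16.6, abs=0.05)

    def test_printed_radius_at_high_tension(self):
        R = equilibrium_radius(16.0, tension_si_to_kbt(5e-4))
        assert R == pytest.approx(8.0, abs=0.15)

    def test_quadrupling_tension_halves_radius(self):
        g = tension_si_to_kbt(1.5e-4)
        assert equilibrium_radius(20.0, 4 * g) == pytest.approx(
            equilibrium_radius(20.0, g) / 2.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_radius(-1.0, 0.1)


class TestModifiedTension:
    def test_constricted_radius_at_defaults_is_3_5(self):
        gamma = tension_si_to_kbt(1.5e-4)
        coat = DynaminCoat(H=200.0, z_0=0.0)
        R_c = constricted_radius(20.0, modified_tension(gamma, coat))
        assert R_c == pytest.approx(3.5, abs=0.05)

    def test_zero_force_recovers_bare_tension(self):
        gamma = tension_si_to_kbt(1.5e-4)
        coat = DynaminCoat(H=200.0, z_0=0.0, F_tau=0.0)
        assert modified_tension(gamma, coat) == gamma
        assert constricted_radius(20.0, gamma) == equilibrium_radius(20.0, gamma)

    def test_hamiltonian_stationary_at_constricted_radius(self):
        gamma_bar = modified_tension(tension_si_to_kbt(1.5e-4),
                                     DynaminCoat(H=200.0, z_0=0.0))
        R_c = constricted_radius(20.0, gamma_bar)
        h = 1e-5
        dH = (cylinder_hamiltonian(R_c + h, 100.0, 20.0, gamma_bar)
              - cylinder_hamiltonian(R_c - h, 100.0, 20.0, gamma_bar)) / (2 * h)
        assert abs(dH) < 1e-6 * cylinder_hamiltonian(R_c, 100.0, 20.0, gamma_bar)


class TestFissionTime:
    def test_alpha_is_two_at_fit_midpoint(self):
        assert alpha_correction(2.318) == pytest.approx(2.0)

    def test_alpha_at_4_pn(self):
        assert alpha_correction(4.0) == pytest.approx(1.0 + math.exp(-2.089), abs=2e-3)
        assert alpha_correction(4.0) == pytest.approx(1.124, abs=1e-3)

    def test_long_coat_fission_time_at_experiment_parameters(self):
        """k_b=16, gamma=5e-4 N/m, N_d x F_tau = 15 x 4 pN: t_f ~ 7 s."""
        coat = DynaminCoat(H=200.0, z_0=0.0, F_tau=4.0, N_d=15)
        t_f = fission_time_prediction(16.0, tension_si_to_kbt(5e-4), coat, 3.57)
        assert t_f == pytest.approx(7.0, rel=0.05)

    def test_short_coat_warns(self):
        coat = DynaminCoat(H=20.0, z_0=0.0)
        with pytest.warns(UserWarning, match="long coats"):
            fission_time_prediction(20.0, tension_si_to_kbt(1.5e-4), coat, 3.57)


class TestMobility:
    def test_printed_sharp_mobility(self):
        assert mobility_sharp(4.04, 5.0 / 6.0) == pytest.approx(3.57, abs=0.005)

    def test_linearity(self):
        assert mobility_sharp(0.0, 1.0) == 0.0
        assert mobility_sharp(4.04, 2 * 5 / 6) == pytest.approx(
            2 * mobility_sharp(4.04, 5 / 6))


class TestGreensFunction:
    def test_value_at_origin(self):
        R = 16.6
        assert greens_function(0.0, R) == pytest.approx(SQRT2 / (4 * R))

    @given(st.floats(-200.0, 200.0), st.floats(5.0, 30.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_even_and_enveloped(self, z, R):
        g_p = float(greens_function(z, R))
        g_m = float(greens_function(-z, R))
        assert g_p == pytest.approx(g_m, rel=1e-12, abs=1e-15)
        envelope = SQRT2 / (2 * R) * math.exp(-abs(z) / (SQRT2 * R))
        assert abs(g_p) <= envelope * (1 + 1e-12)

    def test_unit_integral(self):
        """The zero-mode response of R^4 u'''' + u = delta integrates to 1."""
        R = 16.6
        z = np.linspace(-60 * R, 60 * R, 200001)
        total = np.trapezoid(greens_function(z, R), z)
        assert total == pytest.approx(1.0, rel=1e-6)


class TestLinearDeformation:
    def test_convolution_matches_spectral_ode_solve(self):
        """Closed-form convolution vs independent Fourier solve of the beam-on-
        foundation equation, with the window's exact Fourier coefficients."""
        R, H, k_b = 16.6, 100.0, 20.0
        N = 16384
        z = np.linspace(-900.0, 900.0, N, endpoint=False)
        L = 1800.0
        u = linear_deformation(H, R, k_b, z)
        k = 2 * np.pi * sfft.rfftfreq(N, z[1] - z[0])
        with np.errstate(divide="ignore", invalid="ignore"):
            window_hat = np.where(k == 0, H / L * N, 2 * np.sin(k * H / 2) / (k * L) * N)
        phase = np.exp(-1j * k * z[0])
        u_ode = sfft.irfft(-window_hat * phase / (R**4 * k**4 + 1), n=N)
        assert np.abs(u - u_ode).max() / np.abs(u).max() < 1e-6

    def test_delta_limit_is_greens_function(self):
        R = 16.6
        z = np.linspace(-800.0, 800.0, 8001)
        u = linear_deformation(1e-6, R, 20.0, z)
        g = greens_function(z, R)
        assert np.allclose(-u / 1e-6, g, rtol=1e-4, atol=1e-8)

    def test_short_window_has_single_central_minimum(self):
        R = 16.6
        z = np.linspace(-800.0, 800.0, 32001)
        u = linear_deformation(2 * R, R, 20.0, z)
        assert count_linear_minima(u) == 1
        assert z[np.argmin(u)] == pytest.approx(0.0, abs=z[1] - z[0])

    def test_underresolved_grid_rejected(self):
        with pytest.raises(ValueError):
            linear_deformation(100.0, 16.6, 20.0, np.linspace(-60, 60, 100))


class TestThreshold:
    def test_threshold_value_and_scaling(self):
        assert linear_threshold(16.6) == pytest.approx(2 * SQRT2 * np.pi * 16.6)
        assert linear_threshold(16.6) == pytest.approx(147.5, abs=0.1)
        assert linear_threshold(33.2) == pytest.approx(2 * linear_threshold(16.6))

    @pytest.mark.parametrize("factor,expected", [(0.9, 1), (1.1, 2)])
    def test_minima_count_flips_across_threshold(self, factor, expected):
        R = 16.6
        z = np.linspace(-900.0, 900.0, 65536, endpoint=False)
        u = linear_deformation(factor * linear_threshold(R), R, 20.0, z)
        assert count_linear_minima(u) == expected


class TestShapeEquation:
    def test_cylinder_at_equilibrium_radius_has_zero_residual(self):
        gamma = tension_si_to_kbt(1.5e-4)
        R = equilibrium_radius(20.0, gamma)
        z = np.linspace(0.0, 400.0, 512, endpoint=False)
        res = shape_equation_residual(z, np.full_like(z, R),
                                      np.full_like(z, np.pi / 2),
                                      np.zeros_like(z), 20.0, gamma)
        assert np.abs(res).max() < 1e-12

    def test_linearization_consistency_second_order_in_amplitude(self):
        """For u solving the linear equation the residual is O(alpha^2)."""
        gamma = tension_si_to_kbt(1.5e-4)
        k_b = 20.0
        R = equilibrium_radius(k_b, gamma)
        L = 1024.0
        z = np.linspace(0.0, L, 2048, endpoint=False)
        kz = 2 * np.pi * 3 / L
        # cosine deformation solving R^4 u'''' + u = pbar R^4 / k_b
        u = np.cos(kz * (z - L / 2))
        pbar = k_b / R**4 * (R**4 * kz**4 + 1.0) * u
        residuals = []
        for alpha in (1e-2, 5e-3):
            r_prof = R + alpha * u
            psi = np.pi / 2 - np.arctan(alpha * np.gradient(u, z))
            # use spectral derivative of r for psi to keep periodicity clean
            k = 2 * np.pi * sfft.rfftfreq(z.size, z[1] - z[0])
            du = sfft.irfft(1j * k * sfft.rfft(u), n=z.size)
            psi = np.pi / 2 - np.arctan(alpha * du)
            res = shape_equation_residual(z, r_prof, psi, alpha * pbar, k_b, gamma)
            residuals.append(np.abs(res).max())
        ratio = residuals[0] / residuals[1]
        assert ratio == pytest.approx(4.0, rel=0.3)  # quadratic in alpha

    def test_pressure_enters_linearly(self):
        gamma = tension_si_to_kbt(1.5e-4)
        z = np.linspace(0.0, 400.0, 512, endpoint=False)
        r_prof = np.full_like(z, 10.0)  # off-equilibrium cylinder
        psi = np.full_like(z, np.pi / 2)
        p = 0.01 * np.cos(2 * np.pi * z / 400.0)
        res0 = shape_equation_residual(z, r_prof, psi, np.zeros_like(z), 20.0, gamma)
        res1 = shape_equation_residual(z, r_prof, psi, p, 20.0, gamma)
        res2 = shape_equation_residual(z, r_prof, psi, 2 * p, 20.0, gamma)
        assert np.allclose(res2 - res0, 2 * (res1 - res0), atol=1e-12)


class TestSharpPrediction:
    def test_bundle_consistency(self):
        coat = DynaminCoat(H=200.0, z_0=0.0)
        pred = SharpPrediction.from_parameters(20.0, tension_si_to_kbt(1.5e-4), coat)
        assert pred.R_c < pred.R_in
        assert pred.L_dec == pytest.approx(SQRT2 * pred.R_in)
        assert pred.H_star_le == pytest.approx(2 * SQRT2 * np.pi * pred.R_in)
        assert pred.M_sharp == pytest.approx(3.57, abs=0.005)
        d = pred.as_dict()
        assert set(d) == {"R_in_nm", "gamma_bar_kbt_nm2", "R_c_nm", "H_star_le_nm",
                          "L_dec_nm", "M_sharp_nm4_s_kbt", "alpha", "t_f_s"}
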