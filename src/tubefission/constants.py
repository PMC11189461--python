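"""Unit system and physical constants.

All lengths are in nm, energies in units of the thermal energy k_BT at
T = 298 K, forces in pN and times in seconds.  With these choices every
membrane-elasticity constant of interest (bending rigidity ~20 k_BT,
tension ~1e-4 N/m, power-stroke force ~2.5 pN) is an O(1)-O(100) number
and no further scaling is needed inside the solver.
"""

#: Thermal energy at 298 K expressed in pN*nm (1 k_BT = 4.114 pN*nm).
KBT_PN_NM = 4.114

#: 1 N/m expressed in pN/nm (tension conversion: 1 N/m = 1e12 pN / 1e9 nm).
N_PER_M_TO_PN_PER_NM = 1.0e3


def tension_si_to_kbt(gamma_n_per_m: float) -> float:
    """Convert a surface tension from N/m to k_BT/nm^2."""
    return gamma_n_per_m * N_PER_M_TO_PN_PER_NM / KBT_PN_NM


def tension_kbt_to_si(gamma_kbt_nm2: float) -> float:
    """Convert a surface tension from k_BT/nm^2 to N/m."""
    return gamma_kbt_nm2 * KBT_PN_NM / N_PER_M_TO_PN_PER_NM


def pressure_pn_nm2_to_kbt(p_pn_nm2: float) -> float:
    """Convert a pressure from pN/nm^2 to k_BT/nm^3."""
    return p_pn_nm2 / KBT_PN_NM


def force_pn_to_kbt_per_nm(f_pn: float) -> float:
    """Convert a force from pN to k_BT/nm."""
    return f_pn / KBT_PN_NM
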