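"""Unit system and conversions used throughout the package.

The package works in mV, ms, um, uS (so uS * mV = nA and nF / uS = ms),
cm^2 for membrane areas, Ohm*cm for axial resistivity and V/m for field
amplitudes.  All conversions between these units live here.
"""

from __future__ import annotations

import numpy as np

UM_PER_CM = 1.0e4
UM2_PER_CM2 = 1.0e8


def cylinder_area_cm2(radius_um, length_um):
    """Lateral membrane area of a cylinder, in cm^2."""
    return 2.0 * np.pi * np.asarray(radius_um) * np.asarray(length_um) / UM2_PER_CM2


def half_axial_resistance_Mohm(radius_um, length_um, r_axial_ohm_cm):
    """Axial resistance of half a cylinder (center to end), in MOhm.

    Couplings between adjacent compartments are the series combination of
    the two facing half-resistances.
    """
    r_cm = np.asarray(radius_um) / UM_PER_CM
    half_l_cm = np.asarray(length_um) / 2.0 / UM_PER_CM
    return r_axial_ohm_cm * half_l_cm / (np.pi * r_cm**2) / 1.0e6


def extracellular_mV(e0_V_per_m, coordinate_um):
    """Extracellular potential of a uniform field at a field-axis coordinate.

    A 1 V/m field over 1000 um drops 1 mV.  The sign convention is
    v_e = -E0 * s, so a positive field along the axis depolarizes the end
    with the largest axis coordinate (v = v_i - v_e).
    """
    return -np.asarray(e0_V_per_m) * np.asarray(coordinate_um) * 1.0e-3


def capacitance_nF(c_m_uF_per_cm2, area_cm2):
    return np.asarray(c_m_uF_per_cm2) * np.asarray(area_cm2) * 1.0e3


def conductance_uS(g_S_per_cm2, area_cm2):
    return np.asarray(g_S_per_cm2) * np.asarray(area_cm2) * 1.0e6


def space_constant_um(radius_um, g_l_S_per_cm2, r_axial_ohm_cm):
    """Passive DC space constant lambda = sqrt(r / (2 R_a g_m)), in um."""
    r_cm = np.asarray(radius_um) / UM_PER_CM
    lam_cm = np.sqrt(r_cm / (2.0 * r_axial_ohm_cm * g_l_S_per_cm2))
    return lam_cm * UM_PER_CM


def g_l_for_space_constant(radius_um, lambda_um, r_axial_ohm_cm):
    """Leak density (S/cm^2) that realizes a target DC space constant."""
    r_cm = np.asarray(radius_um) / UM_PER_CM
    lam_cm = np.asarray(lambda_um) / UM_PER_CM
    return r_cm / (2.0 * r_axial_ohm_cm * lam_cm**2)


def tau_ms(c_m_uF_per_cm2, g_l_S_per_cm2):
    """Membrane time constant c_m / g_m, in ms."""
    return np.asarray(c_m_uF_per_cm2) * 1.0e-3 / np.asarray(g_l_S_per_cm2)


def c_m_for_tau(tau_ms_, g_l_S_per_cm2):
    """Specific capacitance (uF/cm^2) that realizes a target time constant."""
    return np.asarray(tau_ms_) * np.asarray(g_l_S_per_cm2) * 1.0e3


def omega_rad_per_ms(frequency_hz):
    """Angular frequency in rad/ms for a frequency in Hz."""
    return 2.0 * np.pi * np.asarray(frequency_hz) * 1.0e-3
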