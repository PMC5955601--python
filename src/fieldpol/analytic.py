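"""Closed-form and semi-analytic passive-cable solutions under uniform fields.

Everything here works in normalized (electrotonic) units: positions and
lengths in units of the DC space constant lambda, sensitivities in V per
(V/lambda).  The frequency enters through the complex space constant

    lambda_eq(f)^2 = lambda^2 / (1 + i w tau),      w = 2 pi f,

whose real part is the generalized space constant lambda_gen(f).  A straight
cable in a uniform field polarizes as

    v(X) = lam sinh((X - L/2)/lam) / cosh(L/(2 lam)),   lam = lambda_eq/lambda,

antisymmetric about the center with maxima at the sealed ends.  The bent
cable sees the continuous piecewise-linear extracellular profile obtained by
projecting the bent branch on the field axis (slope -cos(theta) relative to
the main branch); its polarization is computed exactly by matching hyperbolic
homogeneous solutions at the bend.  These closed forms are the oracles for
the compartmental solver and the engine for the resonance-map analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .resonance import ResonanceSummary, detect_resonance


def _omega_tau(tau_ms: float, f_hz) -> np.ndarray:
    return 2.0 * np.pi * np.asarray(f_hz, dtype=float) * tau_ms * 1.0e-3


def lambda_eq(lambda_um: float, tau_ms: float, f_hz):
    """Complex frequency-dependent space constant (same units as lambda)."""
    if lambda_um <= 0 or tau_ms <= 0:
        raise ValueError("lambda and tau must be positive")
    return lambda_um / np.sqrt(1.0 + 1j * _omega_tau(tau_ms, f_hz))


def lambda_gen(lambda_um: float, tau_ms: float, f_hz):
    """Generalized space constant: Re(lambda_eq); shrinks with frequency."""
    return np.real(lambda_eq(lambda_um, tau_ms, f_hz))


def straight_uniform_sensitivity(L: float, tau_ms: float, f_hz: float, X):
    """Complex polarization of a straight cable in a uniform unit field.

    Normalized units: X, L in lambda; the result in V per (V/lambda).
    Antisymmetric about X = L/2; |value| at the ends is the end sensitivity.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < -1e-12) or np.any(X > L + 1e-12):
        raise ValueError("X must lie within [0, L]")
    lam = lambda_eq(1.0, tau_ms, f_hz)
    return lam * np.sinh((X - L / 2.0) / lam) / np.cosh(L / (2.0 * lam))


# ---------------------------------------------------------------------------
# Green's-function mode solution


@dataclass
class ModeSolution:
    """Sealed-end solution of -V_i'' + V_i = sin(Omega_x X + phi_s) on [0, L]."""

    omega_x: float
    phi_s: float
    L: float
    v_i: Callable
    v: Callable  # V = V_i - V_e
    dv_i: Callable


def greens_mode_solution(omega_x: float, phi_s: float, L: float) -> ModeSolution:
    """Single spatial-frequency mode of the cable response.

    The particular response is sin(Omega_x X + phi_s)/(Omega_x^2 + 1); the
    hyperbolic homogeneous part enforces dV_i/dX = 0 at both sealed ends.
    At Omega_x = 0 the extracellular potential is spatially constant and
    polarizes nothing (V = 0 identically).
    """
    if L <= 0:
        raise ValueError("L must be positive")
    w, p = float(omega_x), float(phi_s)
    pref = 1.0 / (w**2 + 1.0)

    # homogeneous coefficients a cosh X + b sinh X from the sealed ends
    b = -w * np.cos(p) * pref
    a = (-w * np.cos(w * L + p) * pref - b * np.cosh(L)) / np.sinh(L)

    def v_i(X):
        X = np.asarray(X, dtype=float)
        return pref * np.sin(w * X + p) + a * np.cosh(X) + b * np.sinh(X)

    def dv_i(X):
        X = np.asarray(X, dtype=float)
        return pref * w * np.cos(w * X + p) + a * np.sinh(X) + b * np.cosh(X)

    def v(X):
        X = np.asarray(X, dtype=float)
        return v_i(X) - np.sin(w * X + p)

    return ModeSolution(w, p, L, v_i=v_i, v=v, dv_i=dv_i)


# ---------------------------------------------------------------------------
# Bent cable (piecewise-linear extracellular profile)


def bent_extracellular_profile(H: float, D: float, theta: float, x):
    """Normalized extracellular potential v_e(x) = -p(x) for a unit field,
    where p is the field-axis projection of the arc position: slope 1 on the
    main branch, -cos(theta) on the bent branch, continuous at the bend."""
    x = np.asarray(x, dtype=float)
    p = np.where(x <= H, x, H - np.cos(theta) * (x - H))
    return -p


def bent_cable_sensitivity(
    H: float, D: float, theta: float, tau_ms: float, f_hz: float, X
):
    """Complex polarization of a bent cable in a uniform unit field.

    Normalized units (X in lambda over the arc [0, H+D], bend at X = H).
    Solved exactly: v_i = v_e + hyperbolic homogeneous terms per piece,
    matched in value and derivative at the bend, sealed at both ends.
    """
    if H <= 0 or D <= 0:
        raise ValueError("H and D must be positive")
    if not 0 <= theta <= np.pi:
        raise ValueError("theta must lie in [0, pi]")
    X = np.asarray(X, dtype=float)
    if np.any(X < -1e-12) or np.any(X > H + D + 1e-12):
        raise ValueError("X must lie within [0, H+D]")
    lam = lambda_eq(1.0, tau_ms, f_hz)
    l_tot = H + D
    s2 = np.cos(theta)  # v_e slope on the bent branch is +cos(theta) (v_e=-p)
    # v_e slopes: main -1, bent +cos(theta)
    # unknowns [A1, B1, A2, B2]: v_i = v_e + A cosh(x/lam) + B sinh(x/lam)
    ch = np.cosh(H / lam)
    sh = np.sinh(H / lam)
    chl = np.cosh(l_tot / lam)
    shl = np.sinh(l_tot / lam)
    m = np.array(
        [
            [0.0, 1.0 / lam, 0.0, 0.0],  # v_i'(0) = 0
            [0.0, 0.0, shl / lam, chl / lam],  # v_i'(l) = 0
            [ch, sh, -ch, -sh],  # value continuity at the bend
            [sh / lam, ch / lam, -sh / lam, -ch / lam],  # derivative continuity
        ],
        dtype=complex,
    )
    # v_e' jumps from -1 to +cos(theta) at the bend, so the homogeneous parts
    # must jump by the opposite amount to keep v_i in C^1
    rhs = np.array([1.0, -s2, 0.0, 1.0 + s2], dtype=complex)
    a1, b1, a2, b2 = np.linalg.solve(m, rhs)
    v_e = bent_extracellular_profile(H, D, theta, X)
    main = X <= H
    hom = np.where(
        main,
        a1 * np.cosh(X / lam) + b1 * np.sinh(X / lam),
        a2 * np.cosh(X / lam) + b2 * np.sinh(X / lam),
    )
    return hom  # v = v_i - v_e and v_i = v_e + hom


def bent_end_sweep(
    H: float, D: float, theta: float, tau_ms: float, frequencies_hz
) -> np.ndarray:
    """|sensitivity| at the bent-branch end across frequencies."""
    return np.array(
        [abs(complex(bent_cable_sensitivity(H, D, theta, tau_ms, f, H + D)))
         for f in np.asarray(frequencies_hz, dtype=float)]
    )


def resonance_maps(
    H_grid,
    D_grid,
    theta: float,
    tau_ms: float,
    frequencies_hz=None,
    baseline_hz: float = 0.5,
):
    """Bent-end resonance presence, frequency and amplitude over (H, D).

    Returns (present, f_res, amplitude) arrays of shape (len(H), len(D));
    absent cells carry NaN in f_res and amplitude.
    """
    if frequencies_hz is None:
        frequencies_hz = np.logspace(np.log10(baseline_hz), 3, 30)
    H_grid = np.asarray(H_grid, dtype=float)
    D_grid = np.asarray(D_grid, dtype=float)
    present = np.zeros((len(H_grid), len(D_grid)), dtype=bool)
    f_res = np.full_like(present, np.nan, dtype=float)
    amp = np.full_like(present, np.nan, dtype=float)
    for i, h in enumerate(H_grid):
        for j, d in enumerate(D_grid):
            sweep = bent_end_sweep(h, d, theta, tau_ms, frequencies_hz)
            res = detect_resonance(frequencies_hz, sweep, baseline_hz)
            present[i, j] = res.present
            if res.present:
                f_res[i, j] = res.f_res_hz
                amp[i, j] = res.amplitude
    return present, f_res, amp
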