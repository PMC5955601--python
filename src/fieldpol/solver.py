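"""Membrane polarization under uniform DC/AC extracellular fields.

The production path is an exact frequency-domain solve of the linear
(passive / frozen / quasi-active) compartmental system

    (G_axial + diag Y(w)) v_i = diag Y(w) v_e

where Y(w) is the per-compartment complex membrane admittance and
v_e = -E0 (s . e_hat) the extracellular potential of the uniform field.
The field sensitivity at a location is |v_i - v_e| / E0 (mV per V/m).

A Crank-Nicolson time-domain integrator reproduces the simulation protocol
(settle, then field onset; last-peak readout), and a staggered nonlinear
integrator for full single-gate channels serves as a validation oracle for
the quasi-active approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import units
from .membrane import (
    FrozenChannel,
    GatedChannel,
    ModelInstance,
    QAChannel,
    linearize_channel,
)
from .morphology import CompartmentGraph, FieldAxis


@dataclass(frozen=True)
class StimulusSpec:
    """Uniform field: amplitude E0 (V/m), frequency (Hz, 0 = DC), axis."""

    e0: float
    frequency_hz: float
    axis: FieldAxis

    def __post_init__(self):
        if self.e0 < 0:
            raise ValueError("field amplitude must be non-negative")
        if self.frequency_hz < 0:
            raise ValueError("field frequency must be non-negative")


@dataclass
class SensitivityProfile:
    """Per-compartment polarization amplitude per unit field and phase."""

    frequency_hz: float
    amplitude: np.ndarray  # mV per V/m
    phase: np.ndarray  # rad in (-pi, pi], relative to the field sinusoid


@dataclass
class TimeTrace:
    t_ms: np.ndarray
    v_mV: np.ndarray  # (n_locations, n_t) membrane deviation from rest
    stimulus: np.ndarray  # field waveform in V/m
    locations: np.ndarray
    e0: float
    frequency_hz: float


def extracellular_profile(
    graph: CompartmentGraph, axis: FieldAxis, e0: float
) -> np.ndarray:
    """Extracellular potential (mV) of a uniform field at each midpoint.

    v_e = -E0 (midpoint - origin) . direction, zero at the soma centroid.
    """
    s = (graph.midpoint - axis.origin) @ axis.direction
    return units.extracellular_mV(e0, s)


def _qa_channels(model: ModelInstance):
    """Channels as (leak increment density, QA terms); gated channels are
    linearized around the model's resting potential."""
    leak_inc = np.zeros(model.graph.n)
    qa_terms = []  # (mu_star * g_density array, tau_w_r)
    for ch in model.channels:
        if isinstance(ch, GatedChannel):
            ch = linearize_channel(ch, model.v_rest, model.g_l)
        g = model.channel_density(ch)
        if isinstance(ch, FrozenChannel):
            leak_inc += g
        else:
            leak_inc += g * np.broadcast_to(
                np.asarray(ch.w_inf_rest, dtype=float), (model.graph.n,)
            )
            mu_g = np.broadcast_to(
                np.asarray(ch.mu_star, dtype=float), (model.graph.n,)
            ) * g
            if np.any(mu_g != 0):
                qa_terms.append((mu_g, float(ch.tau_w_r)))
    return leak_inc, qa_terms


def _leak_uS(model: ModelInstance) -> np.ndarray:
    leak_inc, _ = _qa_channels(model)
    return (
        units.conductance_uS(model.g_l + leak_inc, model.graph.area_cm2)
        + model.shunt_uS
    )


def membrane_admittance(model: ModelInstance, frequency_hz: float) -> np.ndarray:
    """Complex membrane admittance per compartment (uS):
    Y = i w C + G_leak_eff + sum_ch G_mu / (1 + i w tau_w)."""
    if frequency_hz < 0:
        raise ValueError("frequency must be non-negative")
    omega = units.omega_rad_per_ms(frequency_hz)
    area = model.graph.area_cm2
    leak_inc, qa_terms = _qa_channels(model)
    y = (
        1j * omega * units.capacitance_nF(model.c_m, area)
        + units.conductance_uS(model.g_l + leak_inc, area)
        + model.shunt_uS
    ).astype(complex)
    for mu_g, tau in qa_terms:
        y += units.conductance_uS(mu_g, area) / (1.0 + 1j * omega * tau)
    return y


def solve_frequency(model: ModelInstance, stimulus: StimulusSpec) -> SensitivityProfile:
    """Exact phasor solve of the polarization for a uniform sinusoidal field."""
    graph = model.graph
    v_e = extracellular_profile(graph, stimulus.axis, 1.0)  # unit field
    y = membrane_admittance(model, stimulus.frequency_hz)
    lap = graph.axial_laplacian_uS()
    if stimulus.frequency_hz == 0:
        y = y.real
        if np.all(y == 0):
            raise ValueError("singular system: all membrane conductances are zero")
        a = (lap + sp.diags(y)).tocsc()
        v_i = spla.spsolve(a, y * v_e)
    else:
        a = (lap.astype(complex) + sp.diags(y)).tocsc()
        v_i = spla.spsolve(a, y * v_e)
    v = v_i - v_e
    amplitude = np.abs(v) if stimulus.e0 > 0 else np.zeros(graph.n)
    if stimulus.e0 == 0:
        return SensitivityProfile(stimulus.frequency_hz, amplitude, np.zeros(graph.n))
    phase = np.angle(v)  # relative to the field sinusoid; DC: 0 or pi
    phase = np.where(phase <= -np.pi, phase + 2 * np.pi, phase)
    return SensitivityProfile(stimulus.frequency_hz, np.abs(v), phase)


# ---------------------------------------------------------------------------
# Time-domain integration (linear models)


def solve_time_step(
    model: ModelInstance,
    stimulus: StimulusSpec,
    duration_ms: float,
    dt_ms: float = 0.025,
    record: Optional[Sequence[int]] = None,
    linearize: bool = True,
) -> TimeTrace:
    """Crank-Nicolson integration of the linear system with the field
    switched on at t = 0 (the model starts at rest, i.e. settled).

    Raises for nonlinear gated channels unless ``linearize`` is set; the full
    nonlinear path is :func:`simulate_gated`.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if not linearize and any(isinstance(c, GatedChannel) for c in model.channels):
        raise ValueError(
            "nonlinear gated channels present; pass linearize=True or use "
            "simulate_gated for the nonlinear oracle path"
        )
    graph = model.graph
    n = graph.n
    record = np.arange(n) if record is None else np.asarray(record, dtype=int)
    v_e_x = extracellular_profile(graph, stimulus.axis, stimulus.e0)
    lap = graph.axial_laplacian_uS()
    leak_inc, qa_terms = _qa_channels(model)
    g_eff = units.conductance_uS(model.g_l + leak_inc, graph.area_cm2) + model.shunt_uS
    cap = units.capacitance_nF(model.c_m, graph.area_cm2)
    k = len(qa_terms)
    dim = n * (1 + k)

    # state y = [z, m_1..m_k]; C dz/dt = -(G+L) z - sum G_mu m - (L v_e) s(t)
    blocks_m = sp.lil_matrix((dim, dim))
    a11 = -(lap + sp.diags(g_eff))
    a = sp.lil_matrix((dim, dim))
    a[:n, :n] = a11
    mass = [sp.diags(cap)]
    for j, (mu_g, tau) in enumerate(qa_terms):
        g_mu = units.conductance_uS(mu_g, graph.area_cm2)
        r0, r1 = n * (j + 1), n * (j + 2)
        a[:n, r0:r1] = -sp.diags(g_mu)
        a[r0:r1, :n] = sp.eye(n)
        a[r0:r1, r0:r1] = -sp.eye(n)
        mass.append(tau * sp.eye(n))
    a = a.tocsc()
    m = sp.block_diag(mass).tocsc()

    lhs = (m - (dt_ms / 2.0) * a).tocsc()
    rhs = (m + (dt_ms / 2.0) * a).tocsc()
    lu = spla.splu(lhs)

    f = stimulus.frequency_hz
    omega = units.omega_rad_per_ms(f)
    nt = int(np.round(duration_ms / dt_ms)) + 1
    t = np.arange(nt) * dt_ms
    s = np.ones(nt) if f == 0 else np.sin(omega * t)
    lve = lap @ v_e_x  # forcing enters only through axial coupling of v_e

    y = np.zeros(dim)
    out = np.zeros((len(record), nt))
    b = np.zeros(dim)
    for it in range(1, nt):
        b[:n] = -lve * (s[it - 1] + s[it]) / 2.0
        y = lu.solve(rhs @ y + dt_ms * b)
        out[:, it] = y[record]
    return TimeTrace(
        t_ms=t,
        v_mV=out,
        stimulus=(np.ones(nt) if f == 0 else np.sin(omega * t)) * stimulus.e0,
        locations=record,
        e0=stimulus.e0,
        frequency_hz=f,
    )


def measure_sensitivity_from_trace(trace: TimeTrace, settle_frac: float = 0.0):
    """Protocol readout: |last extremum| of the polarization per unit field
    (AC), or the steady value per unit field (DC).

    Requires >= 2 cycles and >= 400 ms of stimulation for AC traces.
    """
    if trace.e0 <= 0:
        raise ValueError("trace was recorded with zero field amplitude")
    t, v = trace.t_ms, trace.v_mV
    dur = t[-1] - t[0]
    if trace.frequency_hz == 0:
        if dur < 400.0:
            raise ValueError("DC trace shorter than 400 ms")
        tail = v[:, t >= t[-1] - 0.05 * dur]
        return np.abs(tail.mean(axis=1)) / trace.e0
    n_cycles = dur * 1e-3 * trace.frequency_hz
    if n_cycles < 2 or dur < 400.0:
        raise ValueError("AC trace must span >= 2 cycles and >= 400 ms")
    amps = np.empty(v.shape[0])
    for i, row in enumerate(v):
        d = np.diff(row)
        sign = np.sign(d)
        ext = np.nonzero(sign[1:] * sign[:-1] < 0)[0] + 1
        if len(ext) == 0:
            raise ValueError("no extremum found in trace")
        amps[i] = abs(row[ext[-1]])
    return amps / trace.e0


# ---------------------------------------------------------------------------
# Nonlinear oracle path


def simulate_gated(
    model: ModelInstance,
    stimulus: StimulusSpec,
    duration_ms: float,
    dt_ms: float = 0.025,
    record: Optional[Sequence[int]] = None,
    settle_ms: float = 700.0,
) -> TimeTrace:
    """Full nonlinear simulation of single-gate channels (validation oracle).

    Staggered scheme: exact exponential gate update, implicit membrane step.
    The model is first settled for ``settle_ms`` without the field, mirroring
    the measurement protocol; returned traces start at field onset.
    """
    graph = model.graph
    n = graph.n
    record = np.arange(n) if record is None else np.asarray(record, dtype=int)
    v_e_x = extracellular_profile(graph, stimulus.axis, stimulus.e0)
    lap = graph.axial_laplacian_uS().toarray() if n <= 400 else graph.axial_laplacian_uS()
    dense = n <= 400
    cap = units.capacitance_nF(model.c_m, graph.area_cm2)
    g_l = units.conductance_uS(model.g_l, graph.area_cm2) + model.shunt_uS
    # shunts share the leak reversal
    gl_el = units.conductance_uS(model.g_l, graph.area_cm2) * model.e_l + model.shunt_uS * model.e_l

    gated = [c for c in model.channels if isinstance(c, GatedChannel)]
    frozen = [c for c in model.channels if isinstance(c, FrozenChannel)]
    qa = [c for c in model.channels if isinstance(c, QAChannel)]
    if qa:
        raise ValueError("nonlinear oracle handles gated/frozen channels only")
    g_frozen = np.zeros(n)
    gfe = np.zeros(n)
    for c in frozen:
        g = model.channel_density(c)
        g_frozen += units.conductance_uS(g, graph.area_cm2)
        gfe += units.conductance_uS(g, graph.area_cm2) * c.e_rev

    g_ch = [units.conductance_uS(model.channel_density(c), graph.area_cm2) for c in gated]
    vm = model.v_rest.copy()
    w = [np.asarray(c.w_inf(vm), dtype=float).copy() for c in gated]

    f = stimulus.frequency_hz
    omega = units.omega_rad_per_ms(f)
    nt = int(np.round(duration_ms / dt_ms)) + 1
    n_settle = int(np.round(settle_ms / dt_ms))
    t_on = n_settle * dt_ms
    out = np.zeros((len(record), nt))
    t_rec = np.arange(nt) * dt_ms
    v0 = vm.copy()

    for it in range(n_settle + nt):
        t_next = (it + 1) * dt_ms
        if t_next <= t_on:
            s_next = 0.0
        else:
            s_next = 1.0 if f == 0 else np.sin(omega * (t_next - t_on))
        # gate update (exact exponential, gate-frozen-voltage over the step)
        for c, wj in zip(gated, w):
            winf = c.w_inf(vm)
            tau = c.tau_w(vm)
            wj[:] = winf + (wj - winf) * np.exp(-dt_ms / tau)
        g_tot = g_l + g_frozen
        ge = gl_el + gfe
        for c, gj, wj in zip(gated, g_ch, w):
            g_tot = g_tot + gj * wj
            ge = ge + gj * wj * c.e_rev
        ve_next = v_e_x * s_next
        if dense:
            a = np.diag(cap / dt_ms + g_tot) + lap
            rhs = cap / dt_ms * vm + ge - lap @ ve_next
            vm = np.linalg.solve(a, rhs)
        else:
            a = sp.diags(cap / dt_ms + g_tot) + lap
            rhs = cap / dt_ms * vm + ge - lap @ ve_next
            vm = spla.spsolve(a.tocsc(), rhs)
        if it >= n_settle:
            out[:, it - n_settle] = (vm - v0)[record]
    return TimeTrace(
        t_ms=t_rec,
        v_mV=out,
        stimulus=(np.ones(nt) if f == 0 else np.sin(omega * t_rec)) * stimulus.e0,
        locations=record,
        e0=stimulus.e0,
        frequency_hz=f,
    )


# ---------------------------------------------------------------------------
# Point-input measures


def input_resistance(model: ModelInstance, comp_index: int) -> float:
    """Small-signal DC input resistance (MOhm) at a compartment."""
    y = membrane_admittance(model, 0.0).real
    a = (model.graph.axial_laplacian_uS() + sp.diags(y)).tocsc()
    b = np.zeros(model.graph.n)
    b[comp_index] = 1.0  # unit current (nA)
    v = spla.spsolve(a, b)
    return float(v[comp_index])


def transfer_impedance(
    model: ModelInstance,
    comp_a: int,
    comp_b: int,
    frequency_hz: float,
    dc_field: Optional[StimulusSpec] = None,
) -> complex:
    """Transfer impedance Z_ab(f) (complex MOhm) from a unit sinusoidal
    current at ``comp_a`` to the potential at ``comp_b``.

    If a DC field is supplied, the solve is performed on top of the
    field-polarized state and the field-only response subtracted; for these
    linear models superposition makes the result field-independent.
    """
    y = membrane_admittance(model, frequency_hz)
    a = (model.graph.axial_laplacian_uS().astype(complex) + sp.diags(y)).tocsc()
    b = np.zeros(model.graph.n, dtype=complex)
    b[comp_a] = 1.0
    if dc_field is not None:
        v_e = extracellular_profile(model.graph, dc_field.axis, dc_field.e0)
        v_with = spla.spsolve(a, b + y * v_e)
        v_field = spla.spsolve(a, y * v_e)
        return complex(v_with[comp_b] - v_field[comp_b])
    return complex(spla.spsolve(a, b)[comp_b])
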