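"""Membrane models: passive leak, single-gate channels, freezing, the
quasi-active (QA) linearization, conductance distributions, uniform-rest
adjustment, shunts and high-conductance states.

The QA approximation linearizes a voltage-gated current around rest V_R:

    c_m dV/dt = -g_L (gamma_R (V - V_R) + mu m) + I_axial
    tau_w(V_R) dm/dt = V - V_R - m

with gamma_R = 1 + g_w w_inf(V_R) / g_L and
mu = (g_w / g_L)(V_R - E_w) dw_inf/dV(V_R).  The density-normalized type
parameter mu* = mu g_L / g_w = (V_R - E_w) dw_inf/dV(V_R) classifies the
current: restorative (mu* > 0, e.g. I_h) or regenerative (mu* < 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import units
from .morphology import CompartmentGraph

DEFAULT_G_L = 50e-6  # S/cm^2, uniform leak density
DEFAULT_C_M = 1.0  # uF/cm^2
DEFAULT_R_AXIAL = 100.0  # Ohm*cm
DEFAULT_TAU_W = 50.0  # ms, QA gate time constant
DEFAULT_W_INF_REST = 0.5


def _central_diff(f: Callable, v: np.ndarray | float, h: float = 0.01):
    return (f(v + h) - f(v - h)) / (2.0 * h)


@dataclass
class GatedChannel:
    """Single-gate voltage-dependent channel g_w * w(t) * (V - E_w).

    ``w_inf`` and ``tau_w`` must accept numpy arrays; ``dw_inf_dv`` may supply
    the analytic activation slope, else a central difference (step 0.01 mV)
    is used -- the slope sets mu and hence the resonance placement.
    """

    name: str
    g_density: float | np.ndarray  # S/cm^2
    e_rev: float  # mV
    w_inf: Callable
    tau_w: Callable
    dw_inf_dv: Optional[Callable] = None

    def slope(self, v):
        if self.dw_inf_dv is not None:
            return self.dw_inf_dv(v)
        return _central_diff(self.w_inf, np.asarray(v, dtype=float))


def boltzmann_channel(
    name: str,
    g_density,
    e_rev: float,
    v_half: float,
    slope_mV: float,
    tau_w_ms,
) -> GatedChannel:
    """Channel with Boltzmann activation 1/(1+exp(-(V-V_half)/k)) and a
    constant (or callable) gate time constant.  Negative ``slope_mV`` gives a
    hyperpolarization-activated (h-type-like) gate."""

    def w_inf(v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - v_half) / slope_mV))

    def dw(v):
        w = w_inf(v)
        return w * (1.0 - w) / slope_mV

    tau = tau_w_ms if callable(tau_w_ms) else (lambda v, t=float(tau_w_ms): np.full_like(np.asarray(v, dtype=float), t))
    return GatedChannel(name, g_density, e_rev, w_inf, tau, dw)


@dataclass
class FrozenChannel:
    """A channel with its gate clamped at rest: a pure leak increment."""

    name: str
    delta_g_density: float | np.ndarray  # g_w * w_inf(V_R), S/cm^2
    e_rev: float


@dataclass
class QAChannel:
    """Quasi-active channel, parameterized by its density and mu*.

    ``g_density`` is the channel conductance density g_w (S/cm^2),
    ``w_inf_rest`` the gate open fraction at rest (its leak contribution is
    g_w * w_inf_rest), ``mu_star`` the density-normalized current type and
    ``tau_w_r`` the gate time constant at rest (ms).
    """

    name: str
    g_density: float | np.ndarray
    mu_star: float
    tau_w_r: float = DEFAULT_TAU_W
    w_inf_rest: float | np.ndarray = DEFAULT_W_INF_REST
    v_r: float = -70.0

    def gamma_r(self, g_l):
        return 1.0 + np.asarray(self.g_density) * np.asarray(self.w_inf_rest) / np.asarray(g_l)

    def mu(self, g_l):
        return self.mu_star * np.asarray(self.g_density) / np.asarray(g_l)


Channel = GatedChannel | FrozenChannel | QAChannel


def linearize_channel(channel: GatedChannel, v_rest, g_l) -> QAChannel:
    """Linearize a gated channel around rest (quasi-active approximation)."""
    if np.any(np.asarray(g_l) <= 0):
        raise ValueError("leak density must be positive to normalize the QA current")
    v_rest = np.asarray(v_rest, dtype=float)
    w0 = channel.w_inf(v_rest)
    mu_star = (v_rest - channel.e_rev) * channel.slope(v_rest)

    if np.ndim(mu_star) and np.ptp(mu_star) == 0:
        mu_star = float(np.ravel(mu_star)[0])
    tau = channel.tau_w(v_rest)
    tau = float(np.mean(tau)) if np.ndim(tau) else float(tau)
    vr = float(np.mean(v_rest)) if np.ndim(v_rest) else float(v_rest)
    return QAChannel(
        name=f"{channel.name}_qa",
        g_density=channel.g_density,
        mu_star=mu_star,
        tau_w_r=tau,
        w_inf_rest=w0 if np.ndim(w0) else float(w0),
        v_r=vr,
    )


def freeze_channel(channel: GatedChannel, v_rest) -> FrozenChannel:
    """Clamp the gate at its resting value; the channel becomes pure leak."""
    w0 = channel.w_inf(np.asarray(v_rest, dtype=float))
    return FrozenChannel(
        name=f"{channel.name}_frozen",
        delta_g_density=np.asarray(channel.g_density) * w0,
        e_rev=channel.e_rev,
    )


# ---------------------------------------------------------------------------
# Conductance distributions


@dataclass(frozen=True)
class DistributionSpec:
    """Spatial profile for a channel density along the tree.

    ``linear_increasing`` rises affinely with path distance so that the most
    distal apical point has ``ratio`` times the somatic density (the reported
    somato-dendritic I_h gradient); ``linear_decreasing`` uses the reciprocal
    ratio.  All kinds conserve the area-weighted total conductance.
    """

    kind: str = "uniform"
    ratio: float = 60.0

    def __post_init__(self):
        if self.kind not in ("uniform", "linear_increasing", "linear_decreasing"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind != "uniform" and self.ratio <= 1:
            raise ValueError("ratio must exceed 1 for linear distributions")


def distribute_conductance(
    graph: CompartmentGraph, spec: DistributionSpec, g_l: float = DEFAULT_G_L
) -> np.ndarray:
    """Per-compartment channel density (S/cm^2) whose area-weighted total
    equals the total leak conductance."""
    area = graph.area_cm2
    x = graph.path_dist_um
    total = float(np.sum(np.broadcast_to(g_l, (graph.n,)) * area))
    if spec.kind == "uniform":
        return np.full(graph.n, total / area.sum())
    apical = graph.region.astype(str) == "apical"
    if not apical.any():
        raise ValueError("linear distributions need apical compartments")
    x_max = float(x[apical].max())
    if x_max <= 0:
        raise ValueError("all compartments at distance 0: linear profile undefined")
    end_ratio = spec.ratio if spec.kind == "linear_increasing" else 1.0 / spec.ratio
    # g_w(x) = b * (1 + (end_ratio - 1) x / x_max); solve b from conservation
    shape = 1.0 + (end_ratio - 1.0) * x / x_max
    b = total / float(np.sum(shape * area))
    return b * shape


# ---------------------------------------------------------------------------
# Model container


@dataclass
class ModelInstance:
    """A compartment graph with membrane properties attached.

    Densities are per-area (S/cm^2, uF/cm^2) and may be scalars or length-n
    arrays; ``shunt_uS`` holds absolute (area-integrated) leak increments.
    """

    graph: CompartmentGraph
    g_l: np.ndarray  # S/cm^2
    c_m: np.ndarray  # uF/cm^2
    e_l: np.ndarray  # mV
    v_rest: np.ndarray  # mV
    channels: list = field(default_factory=list)
    shunt_uS: np.ndarray = None

    def __post_init__(self):
        n = self.graph.n
        self.g_l = np.broadcast_to(np.asarray(self.g_l, dtype=float), (n,)).copy()
        self.c_m = np.broadcast_to(np.asarray(self.c_m, dtype=float), (n,)).copy()
        self.e_l = np.broadcast_to(np.asarray(self.e_l, dtype=float), (n,)).copy()
        self.v_rest = np.broadcast_to(np.asarray(self.v_rest, dtype=float), (n,)).copy()
        if self.shunt_uS is None:
            self.shunt_uS = np.zeros(n)
        else:
            self.shunt_uS = np.broadcast_to(
                np.asarray(self.shunt_uS, dtype=float), (n,)
            ).copy()

    def copy(self) -> "ModelInstance":
        return ModelInstance(
            graph=self.graph,
            g_l=self.g_l.copy(),
            c_m=self.c_m.copy(),
            e_l=self.e_l.copy(),
            v_rest=self.v_rest.copy(),
            channels=list(self.channels),
            shunt_uS=self.shunt_uS.copy(),
        )

    def channel_density(self, ch) -> np.ndarray:
        g = ch.delta_g_density if isinstance(ch, FrozenChannel) else ch.g_density
        return np.broadcast_to(np.asarray(g, dtype=float), (self.graph.n,))


def build_model(
    graph: CompartmentGraph,
    g_l=DEFAULT_G_L,
    c_m=DEFAULT_C_M,
    e_l: float = -70.0,
    channels: Sequence[Channel] = (),
    v_rest=None,
) -> ModelInstance:
    if v_rest is None:
        v_rest = e_l
    model = ModelInstance(
        graph=graph,
        g_l=g_l,
        c_m=c_m,
        e_l=e_l,
        v_rest=v_rest,
        channels=list(channels),
    )
    if channels:
        set_uniform_rest(model, float(np.mean(model.v_rest)))
    return model


def set_uniform_rest(model: ModelInstance, v_target: float) -> ModelInstance:
    """Adjust E_L per compartment so the leak balances all other membrane
    currents at a uniform resting potential ``v_target`` (in place)."""
    n = model.graph.n
    imbalance = np.zeros(n)  # channel current density at v_target, S/cm^2 * mV
    for ch in model.channels:
        g = model.channel_density(ch)
        if isinstance(ch, GatedChannel):
            imbalance += g * ch.w_inf(np.full(n, v_target)) * (v_target - ch.e_rev)
        elif isinstance(ch, FrozenChannel):
            imbalance += g * (v_target - ch.e_rev)
        else:  # QAChannel: zero current at its linearization point
            ch.v_r = v_target
    e_l = v_target + imbalance / model.g_l
    if not np.all(np.isfinite(e_l)):
        raise ValueError("required leak reversal is not finite")
    model.e_l = e_l
    model.v_rest = np.full(n, float(v_target))
    return model


def add_shunt(model: ModelInstance, comp_index: int, g_shunt_uS: float) -> ModelInstance:
    """Add an absolute (area-integrated) leak conductance at one compartment."""
    if g_shunt_uS < 0:
        raise ValueError("shunt conductance must be non-negative")
    out = model.copy()
    out.shunt_uS[comp_index] += g_shunt_uS
    return out


def add_uniform_conductance(
    model: ModelInstance, delta_g: float, v_rest_target: Optional[float] = None
) -> ModelInstance:
    """Uniformly raise the leak density (high-conductance state), optionally
    re-balancing E_L for a uniform resting potential."""
    if delta_g < 0:
        raise ValueError("conductance increment must be non-negative")
    out = model.copy()
    out.g_l = out.g_l + delta_g
    if v_rest_target is not None:
        set_uniform_rest(out, v_rest_target)
    return out
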