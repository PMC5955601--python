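"""Parametric morphologies for the simplified-model experiments.

Straight cables, bent cables (controlled H, D, theta), soma-star models (a
main "apical" cable with a star of "basal" branches at one end) and a seeded
surrogate pyramidal cell reproducing the structural features the field
response depends on: a long apical trunk parallel to the field axis, a basal
star at the soma, and oblique branches whose tips project beyond their
branch points along the axis.

Electrotonic specifications (lengths in units of the DC space constant
lambda) are realized physically with uniform radius and the membrane
densities solved from lambda = sqrt(r / (2 R_a g_m)) and tau = c_m / g_m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .membrane import DEFAULT_R_AXIAL, ModelInstance, build_model
from .morphology import (
    CompartmentGraph,
    FieldAxis,
    SwcPoint,
    build_compartments,
)

DEFAULT_LAMBDA_UM = 500.0
DEFAULT_TAU_MS = 40.0
DEFAULT_RADIUS_UM = 0.25  # gives g_L = 50 uS/cm^2 at lambda = 500 um, R_a = 100


@dataclass(frozen=True)
class CableSpec:
    """Straight cable by physical length and electrotonic targets."""

    l_um: float = DEFAULT_LAMBDA_UM
    radius_um: float = DEFAULT_RADIUS_UM
    target_lambda_um: float = DEFAULT_LAMBDA_UM
    target_tau_ms: float = DEFAULT_TAU_MS
    r_axial_ohm_cm: float = DEFAULT_R_AXIAL

    def __post_init__(self):
        for v in (self.l_um, self.radius_um, self.target_lambda_um, self.target_tau_ms):
            if v <= 0:
                raise ValueError("cable spec fields must be positive")


@dataclass(frozen=True)
class BentCableSpec:
    """Main branch of electrotonic length H, bent branch D, bend angle theta.

    theta follows the extracellular-projection convention: the bent branch
    direction d satisfies d . e_field = -cos(theta), so theta = pi is a
    straight continuation and theta = 0 a complete fold-back.
    """

    h: float = 0.6
    d: float = 0.4
    theta: float = math.pi / 4
    lambda_um: float = DEFAULT_LAMBDA_UM
    tau_ms: float = DEFAULT_TAU_MS
    radius_um: float = DEFAULT_RADIUS_UM

    def __post_init__(self):
        if self.h <= 0 or self.d <= 0:
            raise ValueError("H and D must be positive")
        if not 0 <= self.theta <= math.pi:
            raise ValueError("theta must lie in [0, pi]")


@dataclass(frozen=True)
class StarSpec:
    """Main cable (electrotonic length H) with a star of branches (length D)
    at one end: one branch always the antiparallel continuation, plus N
    branches at angle theta from the main axis, azimuthally equidistributed."""

    h: float = 2.0
    d: float = 0.5
    n_branches: int = 5
    theta: float = math.pi / 2
    lambda_um: float = DEFAULT_LAMBDA_UM
    tau_ms: float = DEFAULT_TAU_MS
    radius_um: float = DEFAULT_RADIUS_UM

    def __post_init__(self):
        if self.h <= 0 or self.d <= 0:
            raise ValueError("H and D must be positive")
        if self.n_branches < 0:
            raise ValueError("branch count must be >= 0")


@dataclass(frozen=True)
class SurrogatePyramidalSpec:
    """Seeded surrogate pyramidal cell (trunk + tuft, basal star, obliques)."""

    trunk_length_um: float = 800.0
    tuft_branch_count: int = 4
    basal_count: int = 6
    oblique_count: int = 3
    oblique_angle: float = math.pi / 4
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.oblique_angle < math.pi / 2:
            raise ValueError("oblique angle must be acute")


def cable_membrane(spec: CableSpec) -> dict:
    """Membrane densities realizing the cable's (lambda, tau) targets."""
    g_l = float(units.g_l_for_space_constant(
        spec.radius_um, spec.target_lambda_um, spec.r_axial_ohm_cm))
    if g_l <= 0 or not np.isfinite(g_l):
        raise ValueError("cable spec is not realizable (non-positive leak)")
    c_m = float(units.c_m_for_tau(spec.target_tau_ms, g_l))
    return {"g_l": g_l, "c_m": c_m, "r_axial_ohm_cm": spec.r_axial_ohm_cm}


def _swc(rows) -> list[SwcPoint]:
    return [SwcPoint(i + 1, tc, x, y, z, r, par) for i, (tc, x, y, z, r, par) in enumerate(rows)]


def make_straight_cable(spec: CableSpec):
    """Straight cable along +x rooted at the origin.

    Returns (morphology, membrane dict).  The root is a dendrite node (no
    soma), preserving the exact end-to-end antisymmetry of the cable.
    """
    rows = [
        (3, 0.0, 0.0, 0.0, spec.radius_um, -1),
        (3, spec.l_um, 0.0, 0.0, spec.radius_um, 1),
    ]
    return _swc(rows), cable_membrane(spec)


def make_bent_cable(spec: BentCableSpec) -> list[SwcPoint]:
    """Bent cable: main branch from the origin along +x (free end at x=0,
    bend at x = H lambda), bent branch at angle theta."""
    lam = spec.lambda_um
    bend = np.array([spec.h * lam, 0.0, 0.0])
    d_hat = np.array([-math.cos(spec.theta), math.sin(spec.theta), 0.0])
    tip = bend + d_hat * spec.d * lam
    rows = [
        (4, 0.0, 0.0, 0.0, spec.radius_um, -1),
        (4, bend[0], bend[1], bend[2], spec.radius_um, 1),
        (3, tip[0], tip[1], tip[2], spec.radius_um, 2),
    ]
    return _swc(rows)


def make_star_model(spec: StarSpec) -> list[SwcPoint]:
    """Soma-star model rooted at the junction (origin).

    The main ("apical", type 4) cable extends along +x; the parallel
    ("basal") branch is its antiparallel continuation along -x and is written
    first among the branches so that the lowest-index basal tip is the
    parallel one.  The N angled branches satisfy d . x_hat = cos(theta).
    """
    lam = spec.lambda_um
    rows = [
        (4, 0.0, 0.0, 0.0, spec.radius_um, -1),
        (4, spec.h * lam, 0.0, 0.0, spec.radius_um, 1),
        (3, -spec.d * lam, 0.0, 0.0, spec.radius_um, 1),
    ]
    for k in range(spec.n_branches):
        phi = 2.0 * math.pi * k / spec.n_branches
        d_hat = np.array([
            math.cos(spec.theta),
            math.sin(spec.theta) * math.cos(phi),
            math.sin(spec.theta) * math.sin(phi),
        ])
        tip = d_hat * spec.d * lam
        rows.append((3, tip[0], tip[1], tip[2], spec.radius_um, 1))
    return _swc(rows)


def make_surrogate_pyramidal(spec: SurrogatePyramidalSpec) -> list[SwcPoint]:
    """Surrogate pyramidal cell, fully determined by its seed.

    Soma at the origin, apical trunk along +y with a tuft at its end, a basal
    star, and oblique branches leaving the trunk at an acute angle so their
    tips project beyond their branch points on the somato-dendritic axis.
    Randomness is limited to azimuthal angles and branch lengths (+-10%).
    """
    rng = np.random.default_rng(spec.seed)
    rows = [(1, 0.0, 0.0, 0.0, 8.0, -1)]

    def jitter(base):
        return base * (1.0 + 0.1 * (2.0 * rng.random() - 1.0))

    # apical trunk: nodes at oblique attachment points and the trunk end
    n_obl = spec.oblique_count
    fracs = np.linspace(0.3, 0.7, n_obl) if n_obl else np.array([])
    trunk_r = 1.8
    parent = 1
    attach_ids = []
    for frac in fracs:
        y = frac * spec.trunk_length_um
        rows.append((4, 0.0, y, 0.0, trunk_r, parent))
        parent = len(rows)
        attach_ids.append(parent)
    rows.append((4, 0.0, spec.trunk_length_um, 0.0, trunk_r, parent))
    trunk_end = len(rows)

    # tuft
    for k in range(spec.tuft_branch_count):
        phi = 2.0 * math.pi * k / max(1, spec.tuft_branch_count) + 0.3 * rng.random()
        ang = math.radians(30.0)
        length = jitter(250.0)
        d = np.array([math.sin(ang) * math.cos(phi), math.cos(ang), math.sin(ang) * math.sin(phi)])
        tip = np.array([0.0, spec.trunk_length_um, 0.0]) + d * length
        rows.append((4, tip[0], tip[1], tip[2], 1.0, trunk_end))

    # obliques: acute angle to the trunk, tip beyond the branch point in +y
    for aid, frac in zip(attach_ids, fracs):
        phi = 2.0 * math.pi * rng.random()
        length = jitter(150.0)
        a = spec.oblique_angle
        d = np.array([math.sin(a) * math.cos(phi), math.cos(a), math.sin(a) * math.sin(phi)])
        base = np.array([0.0, frac * spec.trunk_length_um, 0.0])
        tip = base + d * length
        rows.append((4, tip[0], tip[1], tip[2], 0.8, aid))

    # basal star
    for k in range(spec.basal_count):
        phi = 2.0 * math.pi * k / max(1, spec.basal_count) + 0.3 * rng.random()
        ang = math.radians(120.0)
        length = jitter(180.0)
        d = np.array([math.sin(ang) * math.cos(phi), math.cos(ang), math.sin(ang) * math.sin(phi)])
        tip = d * length
        rows.append((3, tip[0], tip[1], tip[2], 1.2, 1))
    return _swc(rows)


# ---------------------------------------------------------------------------
# Convenience: spec -> ready-to-solve model


def _bound_um(lambda_um: float) -> float:
    return min(10.0, 0.01 * lambda_um)


def straight_cable_model(spec: CableSpec, max_length_um=None) -> tuple[ModelInstance, FieldAxis]:
    pts, mem = make_straight_cable(spec)
    bound = max_length_um or _bound_um(spec.target_lambda_um)
    graph = build_compartments(pts, bound, mem["r_axial_ohm_cm"])
    model = build_model(graph, g_l=mem["g_l"], c_m=mem["c_m"])
    axis = FieldAxis(direction=np.array([1.0, 0.0, 0.0]), origin=np.zeros(3))
    return model, axis


def _cable_spec_for(lambda_um, tau_ms, radius_um) -> CableSpec:
    return CableSpec(
        l_um=lambda_um, radius_um=radius_um,
        target_lambda_um=lambda_um, target_tau_ms=tau_ms,
    )


def bent_cable_model(spec: BentCableSpec, max_length_um=None) -> tuple[ModelInstance, FieldAxis]:
    pts = make_bent_cable(spec)
    mem = cable_membrane(_cable_spec_for(spec.lambda_um, spec.tau_ms, spec.radius_um))
    bound = max_length_um or _bound_um(spec.lambda_um)
    graph = build_compartments(pts, bound, mem["r_axial_ohm_cm"])
    model = build_model(graph, g_l=mem["g_l"], c_m=mem["c_m"])
    axis = FieldAxis(direction=np.array([1.0, 0.0, 0.0]), origin=np.zeros(3))
    return model, axis


def star_model(spec: StarSpec, max_length_um=None) -> tuple[ModelInstance, FieldAxis]:
    pts = make_star_model(spec)
    mem = cable_membrane(_cable_spec_for(spec.lambda_um, spec.tau_ms, spec.radius_um))
    bound = max_length_um or _bound_um(spec.lambda_um)
    graph = build_compartments(pts, bound, mem["r_axial_ohm_cm"])
    model = build_model(graph, g_l=mem["g_l"], c_m=mem["c_m"])
    axis = FieldAxis(direction=np.array([1.0, 0.0, 0.0]), origin=np.zeros(3))
    return model, axis
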