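"""SWC morphologies, compartmentalization and the somato-dendritic field axis.

A morphology is an ordered list of :class:`SwcPoint` (standard 7-column SWC).
:func:`build_compartments` turns it into a :class:`CompartmentGraph`, a tree of
cylindrical compartments with membrane areas, midpoint coordinates, path
distances and axial couplings; this is the container every solver operates on.
:func:`compute_field_axis` computes the somato-dendritic axis as the
volume-weighted vector from the soma centroid to the neurite center of mass,
which is the field orientation studied throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from . import units

SWC_REGIONS = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
REGION_NAMES = ("soma", "basal", "apical", "axon")


class SwcError(ValueError):
    """Malformed or structurally invalid SWC input."""


@dataclass(frozen=True)
class SwcPoint:
    """One SWC sample: id, type code, position (um), radius (um), parent id."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def region(self) -> str:
        # unknown type codes are treated as dendrite (basal) for area purposes
        return SWC_REGIONS.get(self.type_code, "basal")


@dataclass(frozen=True)
class FieldAxis:
    """Unit field direction and the origin (soma centroid) of the potential gauge."""

    direction: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))


@dataclass(frozen=True)
class Compartment:
    """Read-only view of a single compartment (spec-level record)."""

    index: int
    section_id: int
    region: str
    midpoint: tuple
    length: float
    diameter: float
    area: float
    axial_conductance_to_parent: float
    path_distance_to_soma: float


@dataclass
class CompartmentGraph:
    """Tree of cylindrical compartments.

    Arrays are aligned; ``parent[i] == -1`` marks the root.  ``g_axial_uS`` is
    the coupling conductance between compartment ``i`` and its parent
    (series combination of the facing half-cylinder resistances).
    """

    parent: np.ndarray
    region: np.ndarray
    section_id: np.ndarray
    midpoint: np.ndarray
    length_um: np.ndarray
    radius_um: np.ndarray
    area_cm2: np.ndarray
    path_dist_um: np.ndarray
    g_axial_uS: np.ndarray
    r_axial_ohm_cm: float

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def total_area_cm2(self) -> float:
        return float(self.area_cm2.sum())

    def compartment(self, i: int) -> Compartment:
        return Compartment(
            index=i,
            section_id=int(self.section_id[i]),
            region=str(self.region[i]),
            midpoint=tuple(self.midpoint[i]),
            length=float(self.length_um[i]),
            diameter=2.0 * float(self.radius_um[i]),
            area=float(self.area_cm2[i]),
            axial_conductance_to_parent=float(self.g_axial_uS[i]),
            path_distance_to_soma=float(self.path_dist_um[i]),
        )

    def axial_laplacian_uS(self) -> sp.csr_matrix:
        """Graph Laplacian of axial couplings: (L v)_i = sum_j g_ij (v_i - v_j)."""
        n = self.n
        rows, cols, vals = [], [], []
        for i in range(n):
            p = self.parent[i]
            if p < 0:
                continue
            g = self.g_axial_uS[i]
            rows += [i, p, i, p]
            cols += [i, p, p, i]
            vals += [g, g, -g, -g]
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


# ---------------------------------------------------------------------------
# SWC I/O


def read_swc(path) -> list[SwcPoint]:
    """Read a standard 7-column SWC file ('#' comments allowed)."""
    points: list[SwcPoint] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SwcError(f"line {lineno}: expected 7 columns, got {len(cols)}")
            try:
                pid, tc = int(cols[0]), int(cols[1])
                x, y, z, r = (float(c) for c in cols[2:6])
                par = int(cols[6])
            except ValueError as exc:
                raise SwcError(f"line {lineno}: {exc}") from None
            points.append(SwcPoint(pid, tc, x, y, z, r, par))
    validate_morphology(points)
    return points


def write_swc(points: Sequence[SwcPoint], path) -> None:
    with open(path, "w") as fh:
        for p in points:
            fh.write(
                f"{p.id} {p.type_code} {p.x:.6f} {p.y:.6f} {p.z:.6f} "
                f"{p.radius:.6f} {p.parent}\n"
            )


def validate_morphology(points: Sequence[SwcPoint]) -> None:
    """Check the SwcPoint invariants: positive radii, a single root, parents
    preceding children (which also rules out cycles)."""
    if not points:
        raise SwcError("empty morphology")
    seen: set[int] = set()
    roots = 0
    for p in points:
        if p.radius <= 0:
            raise SwcError(f"point {p.id}: non-positive radius")
        if p.id in seen:
            raise SwcError(f"duplicate point id {p.id}")
        if p.parent == -1:
            roots += 1
        elif p.parent not in seen:
            raise SwcError(
                f"point {p.id}: parent {p.parent} does not precede it (forward "
                "reference, missing parent, or cycle)"
            )
        seen.add(p.id)
    if roots != 1:
        raise SwcError(f"expected exactly one root, found {roots}")


# ---------------------------------------------------------------------------
# Compartmentalization


def build_compartments(
    points: Sequence[SwcPoint],
    max_length_um: float = 10.0,
    r_axial_ohm_cm: float = 100.0,
) -> CompartmentGraph:
    """Discretize a morphology into compartments of length <= ``max_length_um``.

    Each SWC edge (parent -> child sample) becomes a chain of equal
    sub-cylinders with the child's radius.  A type-1 root is represented by a
    single equivalent cylinder with length = diameter = 2 * max soma radius.
    Couplings use center-to-center half-resistances, which is the standard
    second-order finite-volume discretization of the cable equation.
    """
    validate_morphology(points)
    if max_length_um < 1e-6:
        raise ValueError("compartment length bound below numeric resolution")

    by_id = {p.id: p for p in points}
    root = next(p for p in points if p.parent == -1)
    soma_pts = [p for p in points if p.type_code == 1]

    parent, region, section_id = [], [], []
    midpoint, length, radius, area, pathd, gax = [], [], [], [], [], []
    # per-compartment half axial resistance, for couplings at junctions
    half_res: list[float] = []
    # SWC node id -> (compartment index, path distance of the node)
    node_comp: dict[int, int] = {}
    node_dist: dict[int, float] = {}
    node_pos: dict[int, np.ndarray] = {}

    if soma_pts:
        r_soma = max(p.radius for p in soma_pts)
        centroid = np.mean([p.xyz for p in soma_pts], axis=0)
        parent.append(-1)
        region.append("soma")
        section_id.append(root.id)
        midpoint.append(centroid)
        length.append(2.0 * r_soma)
        radius.append(r_soma)
        area.append(float(units.cylinder_area_cm2(r_soma, 2.0 * r_soma)))
        pathd.append(0.0)
        gax.append(0.0)
        half_res.append(
            float(units.half_axial_resistance_Mohm(r_soma, 2.0 * r_soma, r_axial_ohm_cm))
        )
        for p in soma_pts:
            node_comp[p.id] = 0
            node_dist[p.id] = 0.0
            node_pos[p.id] = centroid
    else:
        node_dist[root.id] = 0.0
        node_pos[root.id] = root.xyz

    for p in points:
        if p.parent == -1 or p.type_code == 1:
            continue  # root handled above; soma-soma edges absorbed in the cylinder
        if p.parent not in node_pos and p.parent not in node_comp:
            # parent is a soma point not yet registered (no soma block built)
            node_pos[p.parent] = by_id[p.parent].xyz
            node_dist[p.parent] = 0.0
        prox = node_pos[p.parent]
        vec = p.xyz - prox
        elen = float(np.linalg.norm(vec))
        if elen < 1e-9:
            raise SwcError(f"zero-length section at point {p.id}")
        u = vec / elen
        k = max(1, int(np.ceil(elen / max_length_um - 1e-9)))
        sub = elen / k
        hr = float(units.half_axial_resistance_Mohm(p.radius, sub, r_axial_ohm_cm))
        prev = node_comp.get(p.parent, -1)
        prev_hr = half_res[prev] if prev >= 0 else None
        d0 = node_dist[p.parent]
        for j in range(k):
            idx = len(parent)
            parent.append(prev)
            region.append(p.region)
            section_id.append(p.id)
            midpoint.append(prox + u * (j + 0.5) * sub)
            length.append(sub)
            radius.append(p.radius)
            area.append(float(units.cylinder_area_cm2(p.radius, sub)))
            pathd.append(d0 + (j + 0.5) * sub)
            if prev < 0:
                gax.append(0.0)
            else:
                gax.append(1.0 / (hr + prev_hr))
            half_res.append(hr)
            prev, prev_hr = idx, hr
            if j == 0 and p.parent not in node_comp:
                # non-soma root node: the first compartment of its first edge
                # anchors the tree; siblings couple through it (half + half
                # resistance equals the through-node resistance exactly)
                node_comp[p.parent] = idx
        node_comp[p.id] = prev
        node_dist[p.id] = d0 + elen
        node_pos[p.id] = p.xyz

    if not parent:
        raise SwcError("morphology produced no compartments")
    graph = CompartmentGraph(
        parent=np.asarray(parent, dtype=int),
        region=np.asarray(region, dtype=object),
        section_id=np.asarray(section_id, dtype=int),
        midpoint=np.asarray(midpoint, dtype=float),
        length_um=np.asarray(length, dtype=float),
        radius_um=np.asarray(radius, dtype=float),
        area_cm2=np.asarray(area, dtype=float),
        path_dist_um=np.asarray(pathd, dtype=float),
        g_axial_uS=np.asarray(gax, dtype=float),
        r_axial_ohm_cm=r_axial_ohm_cm,
    )
    return graph


# ---------------------------------------------------------------------------
# Field axis


def soma_centroid(points: Sequence[SwcPoint]) -> np.ndarray:
    soma = [p.xyz for p in points if p.type_code == 1]
    if not soma:
        raise SwcError("morphology has no soma points")
    return np.mean(soma, axis=0)


def compute_field_axis(
    points: Sequence[SwcPoint], include_axon: bool = False
) -> FieldAxis:
    """Somato-dendritic axis: unit vector from the soma centroid to the
    volume-weighted center of mass of the neurites."""
    validate_morphology(points)
    origin = soma_centroid(points)
    by_id = {p.id: p for p in points}
    com = np.zeros(3)
    mass = 0.0
    for p in points:
        if p.parent == -1 or p.type_code == 1:
            continue
        if p.type_code == 2 and not include_axon:
            continue
        par = by_id[p.parent]
        prox = origin if par.type_code == 1 else par.xyz
        seg = p.xyz - prox
        elen = float(np.linalg.norm(seg))
        vol = np.pi * p.radius**2 * elen
        com += vol * (prox + p.xyz) / 2.0
        mass += vol
    if mass <= 0:
        raise SwcError("morphology has no neurite mass for the field axis")
    com /= mass
    vec = com - origin
    scale = max(1.0, float(np.max(np.abs([q.xyz for q in points]))))
    norm = float(np.linalg.norm(vec))
    if norm < 1e-9 * scale:
        raise SwcError("degenerate field axis: center of mass coincides with soma")
    return FieldAxis(direction=vec / norm, origin=origin)


# ---------------------------------------------------------------------------
# Membrane-area (spine) scaling


def scale_membrane_area(
    graph: CompartmentGraph,
    factor: float,
    regions: Iterable[str] = ("basal", "apical"),
) -> CompartmentGraph:
    """Scale effective membrane area of selected regions (spine correction).

    Multiplying the area by ``factor`` scales every per-area conductance and
    the capacitance of those compartments equivalently; geometry (lengths,
    radii, axial couplings) is unchanged.
    """
    if factor <= 0:
        raise ValueError("area scale factor must be positive")
    regions = tuple(regions)
    for r in regions:
        if r not in REGION_NAMES:
            raise ValueError(f"unknown region {r!r}; expected one of {REGION_NAMES}")
    mask = np.isin(graph.region.astype(str), regions)
    new_area = graph.area_cm2.copy()
    new_area[mask] *= factor
    return replace(graph, area_cm2=new_area)
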