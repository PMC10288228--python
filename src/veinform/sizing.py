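"""Member sizing from force magnitudes and boundary completion.

Maxwell reciprocity makes the axial force in each member proportional
to the length of its dual edge, so member diameters are sized as
``d = k * F`` with ``k`` fixed by matching the thickest member of the
real wing.  Agreement with measured vein widths is scored on normalized
radii: ``theta = 1 - |R_real - R_generated|`` per member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .errors import AlignmentError, GeometryError, PreconditionError
from .network import PlanarNetwork
from .reciprocal import ForceDiagram, _left_right_faces


@dataclass
class MemberSizing:
    """Per-edge forces, diameters and normalized radii of the internal
    network."""

    force: dict[int, float]
    diameter: dict[int, float]
    normalized_radius: dict[int, float]
    k: float
    d_max: float
    d_min: float
    zero_force_edges: list[int] = field(default_factory=list)

    @property
    def radius(self) -> dict[int, float]:
        return {e: d / 2.0 for e, d in self.diameter.items()}


@dataclass
class ThicknessAccuracy:
    """theta = 1 - |R_real - R_generated| per edge, on normalized radii."""

    per_edge_theta: dict[int, float]
    mean_theta: float
    min_theta: float
    weighted_mean_theta: float | None = None


@dataclass
class VirtualLoadSet:
    """External loads applied at boundary vertices to close every force
    polygon of the otherwise unsupported periphery."""

    loads: dict[int, tuple[float, float]]
    residual_norm: float
    boundary_force: dict[int, float] = field(default_factory=dict)


def size_members(
    force: ForceDiagram, d_max: float, d_min: float | None = None
) -> MemberSizing:
    """Size internal members in strict proportion to dual edge lengths.

    The force diagram is scaled so the largest force maps to ``d_max``;
    zero-force members (possible after T-to-Y repair) are floored at
    ``d_min`` (default ``d_max / 20``) for export and flagged.
    """
    if d_max <= 0:
        raise PreconditionError("d_max must be positive")
    if d_min is None:
        d_min = d_max / 20.0
    F = force.edge_lengths()
    if not F:
        raise PreconditionError("force diagram has no edges to size")
    f_max = max(F.values())
    if f_max <= 0:
        raise GeometryError("all dual edges have zero length")
    k = d_max / f_max
    diameter, zero = {}, []
    for eid, f in F.items():
        d = k * f
        if f <= 1e-12 * f_max:
            zero.append(eid)
            d = d_min
        diameter[eid] = d
    r_max = max(diameter.values()) / 2.0
    return MemberSizing(
        force=F,
        diameter=diameter,
        normalized_radius={e: (d / 2.0) / r_max for e, d in diameter.items()},
        k=k,
        d_max=d_max,
        d_min=d_min,
        zero_force_edges=zero,
    )


def normalized_radii(widths: dict[int, float]) -> dict[int, float]:
    """Normalize measured widths (diameters) to R = r / r_max."""
    w_max = max(widths.values())
    if w_max <= 0:
        raise PreconditionError("widths must contain a positive maximum")
    return {e: w / w_max for e, w in widths.items()}


def thickness_accuracy(
    real_widths: dict[int, float],
    sized: MemberSizing,
    edge_lengths: dict[int, float] | None = None,
) -> ThicknessAccuracy:
    """Score per-member thickness agreement on normalized radii.

    Reports the unweighted mean of per-edge theta and, when form edge
    lengths are supplied, the edge-length-weighted mean as well.
    """
    gen = sized.normalized_radius
    missing_real = sorted(set(gen) - set(real_widths))
    missing_gen = sorted(set(real_widths) - set(gen))
    if missing_real or missing_gen:
        raise AlignmentError(
            f"edge sets differ: missing measured widths {missing_real}, "
            f"missing generated members {missing_gen}"
        )
    if min(real_widths.values()) <= 0:
        raise PreconditionError("real widths must be positive")
    r_real = normalized_radii(real_widths)
    theta = {e: 1.0 - abs(r_real[e] - gen[e]) for e in gen}
    vals = np.array(list(theta.values()))
    weighted = None
    if edge_lengths is not None:
        w = np.array([edge_lengths[e] for e in theta])
        weighted = float(np.average(vals, weights=w))
    return ThicknessAccuracy(
        per_edge_theta=theta,
        mean_theta=float(vals.mean()),
        min_theta=float(vals.min()),
        weighted_mean_theta=weighted,
    )


# ---------------------------------------------------------------------------
# virtual boundary forces


def member_axial_forces(force: ForceDiagram) -> dict[int, float]:
    """Signed axial force per interior form edge (positive = tension),
    from dual edge lengths and the recorded perpendicularity sign."""
    return {de.form_edge_id: de.sign * force.edge_length(de) for de in force.edges}


def virtual_boundary_forces(
    form: PlanarNetwork,
    force: ForceDiagram,
    internal_sizing: MemberSizing,
    boundary_widths: dict[int, float],
    boundary_sense: int = 1,
) -> tuple[VirtualLoadSet, dict[int, list[tuple[float, float]]]]:
    """External loads at the periphery closing every boundary node.

    Boundary member forces are set proportional to their measured
    widths with the same scale ``k`` as the internal sizing; the virtual
    load at each boundary vertex is minus the vector sum of its incident
    member forces, so every boundary force polygon closes and global
    force and moment equilibrium hold identically.  Returns the load set
    and, per boundary vertex, the closed force polygon (vertex chain).
    """
    boundary_edges = [e for e in form.edges if e.boundary]
    missing = sorted(e.id for e in boundary_edges if e.id not in boundary_widths)
    if missing:
        raise PreconditionError(f"boundary widths missing for edges {missing}")
    axial = member_axial_forces(force)
    for e in boundary_edges:
        axial[e.id] = boundary_sense * boundary_widths[e.id] / internal_sizing.k

    inc = form.vertex_edges()
    outer_loop = form.outer_face.loop
    loads: dict[int, tuple[float, float]] = {}
    polygons: dict[int, list[tuple[float, float]]] = {}
    for v in outer_loop:
        p = form.coords(v)
        vectors = []
        for e in sorted(inc[v], key=lambda e: e.id):
            if e.id not in axial:
                continue  # interior edge without dual (not expected)
            w = e.b if e.a == v else e.a
            d = form.coords(w) - p
            d = d / np.hypot(*d)
            vectors.append(axial[e.id] * d)
        total = np.sum(vectors, axis=0) if vectors else np.zeros(2)
        loads[v] = (-float(total[0]), -float(total[1]))
        chain = [(0.0, 0.0)]
        acc = np.zeros(2)
        for vec in vectors + [np.asarray(loads[v])]:
            acc = acc + vec
            chain.append((float(acc[0]), float(acc[1])))
        polygons[v] = chain

    net_force = np.sum([loads[v] for v in loads], axis=0)
    centroid = np.mean([form.coords(v) for v in loads], axis=0)
    net_moment = 0.0
    for v in loads:
        r = form.coords(v) - centroid
        net_moment += float(r[0] * loads[v][1] - r[1] * loads[v][0])
    residual = float(np.hypot(*net_force) + abs(net_moment))
    return (
        VirtualLoadSet(loads=loads, residual_norm=residual,
                       boundary_force={e.id: axial[e.id] for e in boundary_edges}),
        polygons,
    )


# ---------------------------------------------------------------------------
# unified (Minkowski sum) diagram


@dataclass
class UnifiedDiagram:
    """Form and scaled force diagram combined by Minkowski sum.

    Every point is ``x_v + scale * x_dual``: cells keep their shape and
    translate apart, interior members become parallelograms of width
    proportional to their force, and each internal node grows into its
    (scaled) force polygon.  For a valid scale the three families tile
    the combined region with no overlaps.
    """

    cells: dict[int, Polygon]
    members: dict[int, Polygon]
    nodes: dict[int, Polygon]
    scale: float

    def all_polygons(self) -> list[Polygon]:
        return list(self.cells.values()) + list(self.members.values()) + list(self.nodes.values())

    def total_area(self) -> float:
        return float(sum(p.area for p in self.all_polygons()))

    def union_area(self) -> float:
        return float(unary_union(self.all_polygons()).area)


def minkowski_unified(
    form: PlanarNetwork,
    force: ForceDiagram,
    scale: float,
    validate: bool = True,
    rel_tol: float = 1e-6,
) -> UnifiedDiagram:
    """Combine a reciprocal pair into the unified thickened diagram."""
    lr = _left_right_faces(form)
    dual_by_eid = {de.form_edge_id: de for de in force.edges}

    def pt(v: int, f: int) -> tuple[float, float]:
        p = form.coords(v) + scale * force.coords(f)
        return (float(p[0]), float(p[1]))

    cells = {
        f.id: Polygon([pt(v, f.id) for v in f.loop]) for f in form.internal_faces
    }
    members = {}
    for de in force.edges:
        fe = form.edge_by_id(de.form_edge_id)
        fl, fr = lr[fe.id]
        quad = Polygon(
            [pt(fe.a, fl.id), pt(fe.b, fl.id), pt(fe.b, fr.id), pt(fe.a, fr.id)]
        )
        members[de.form_edge_id] = quad

    # node polygon: the vertex's dual face (faces around it in cyclic order)
    nodes = {}
    inc = form.vertex_edges()
    for v in form.internal_vertices():
        p = form.coords(v)
        around = []
        for e in inc[v]:
            fl, fr = lr[e.id]
            for f in (fl, fr):
                if f is not None and not f.is_outer and f.id not in around:
                    around.append(f.id)
        # order faces by angle of their dual vertex around the node's dual face
        ctr = np.mean([force.coords(f) for f in around], axis=0)
        around.sort(
            key=lambda f: math.atan2(*(force.coords(f) - ctr)[::-1])
        )
        poly = Polygon([pt(v, f) for f in around])
        if scale != 0 and poly.area > 0:
            nodes[v] = poly

    uni = UnifiedDiagram(cells=cells, members=members, nodes=nodes, scale=scale)
    if validate and scale != 0:
        bad = [
            eid for eid, poly in members.items() if not poly.is_valid or poly.area <= 0
        ]
        if bad:
            raise GeometryError(
                f"member polygons {bad} are degenerate; use a smaller scale"
            )
        total, union = uni.total_area(), uni.union_area()
        if union <= 0 or abs(total - union) > rel_tol * max(total, union) + 1e-12:
            raise GeometryError(
                "unified diagram polygons overlap (cells invert); "
                f"sum of areas {total:.6g} != union {union:.6g}; use a smaller scale"
            )
    return uni
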