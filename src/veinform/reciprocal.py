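"""Reciprocal (Maxwell) form/force diagram machinery.

The *form diagram* is the planar vein network; its *force diagram* is
the topological dual drawn so that every dual edge is perpendicular to
its corresponding form edge.  Dual edge lengths are then member force
magnitudes and each closed dual face is the force polygon (equilibrium)
of one internal form node.

The drawing is found by alternating projection between two linear
subspaces of edge-vector fields: fields that are perpendicular edge by
edge, and fields that are consistent (realizable as differences of
vertex positions).  Each iteration literally rotates every dual edge
onto its perpendicular target and then reassembles vertex positions by
a least-squares (graph Laplacian) solve, so the distance to both
subspaces is non-increasing and the iteration converges to an exact
reciprocal whenever one exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import GeometryError, PreconditionError, RepairError
from .network import Edge, Face, PlanarNetwork, build_faces, rebuild_faces


def rot90(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector by +90 degrees (CCW)."""
    return np.array([-v[..., 1], v[..., 0]]).T if v.ndim > 1 else np.array([-v[1], v[0]])


# ---------------------------------------------------------------------------
# domain types


@dataclass
class DualEdge:
    """One force-diagram edge, corresponding to one interior form edge.

    ``a``/``b`` are internal form face ids (= dual vertex ids): ``a`` is
    the face to the left of the oriented form edge, ``b`` the face to
    the right.
    """

    id: int
    form_edge_id: int
    a: int
    b: int
    sign: int = 1  # +1: dual vector ~ +90deg rotation of form vector


@dataclass
class ForceDiagram:
    """The reciprocal dual of a form diagram.

    Dual vertex ids coincide with the internal face ids of the form;
    dual edge ids coincide with the interior form edge ids they
    correspond to.
    """

    form: PlanarNetwork
    vertices: dict[int, tuple[float, float]]
    edges: list[DualEdge]
    scale: float = 1.0

    def coords(self, vid: int) -> np.ndarray:
        return np.asarray(self.vertices[vid], dtype=float)

    def edge_vector(self, de: DualEdge) -> np.ndarray:
        return self.coords(de.b) - self.coords(de.a)

    def edge_length(self, de: DualEdge) -> float:
        return float(np.hypot(*self.edge_vector(de)))

    def edge_lengths(self) -> dict[int, float]:
        """Map form edge id -> dual edge length (force magnitude)."""
        return {de.form_edge_id: self.edge_length(de) for de in self.edges}

    def copy(self) -> "ForceDiagram":
        return ForceDiagram(
            form=self.form,
            vertices={v: tuple(p) for v, p in self.vertices.items()},
            edges=[DualEdge(d.id, d.form_edge_id, d.a, d.b, d.sign) for d in self.edges],
            scale=self.scale,
        )


@dataclass
class DeviationStats:
    """Per-edge angular deviations delta from perpendicularity, degrees."""

    per_edge_delta: dict[int, float] = field(default_factory=dict)
    mean_delta: float = 0.0
    max_delta: float = 0.0
    iterations: int = 0
    converged: bool = True
    history: list[float] = field(default_factory=list)
    #: perpendicularity defect (L2 norm of the tangential edge-field
    #: component) per iteration; provably non-increasing for the
    #: alternating-projection scheme
    residual_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# convexity helpers


def face_turns(net: PlanarNetwork, face: Face) -> np.ndarray:
    """Normalized cross products of consecutive edge vectors of a loop."""
    pts = np.array([net.vertices[v] for v in face.loop], dtype=float)
    vec = np.roll(pts, -1, axis=0) - pts
    nrm = np.linalg.norm(vec, axis=1)
    cross = vec[:, 0] * np.roll(vec[:, 1], -1) - vec[:, 1] * np.roll(vec[:, 0], -1)
    denom = nrm * np.roll(nrm, -1)
    denom[denom == 0] = np.inf
    return cross / denom


def is_convex_face(net: PlanarNetwork, face: Face, tol: float = 1e-12) -> bool:
    """True if a CCW internal face loop is convex (all left turns)."""
    return bool(np.all(face_turns(net, face) > tol))


# ---------------------------------------------------------------------------
# T -> Y joint repair


def repair_t_joints(
    net: PlanarNetwork, epsilon: float = 0.01, collinear_tol_deg: float = 2.0
) -> PlanarNetwork:
    """Offset degree-3 vertices with two collinear edges (T joints).

    A member meeting a straight through-vein at a T carries no force in
    any planar equilibrium, so the junction is nudged perpendicular to
    the through-line by ``epsilon`` times the mean incident edge length,
    turning the T into a Y.  Topology is unchanged.
    """
    out = net.copy()
    inc = out.vertex_edges()
    moved = []
    for v, edges in inc.items():
        if len(edges) != 3:
            continue
        p = out.coords(v)
        dirs, lens = [], []
        for e in edges:
            w = e.b if e.a == v else e.a
            d = out.coords(w) - p
            length = np.hypot(*d)
            dirs.append(d / length)
            lens.append(length)
        # find the collinear pair (angle within 180 +- tol)
        pair = None
        for i in range(3):
            for j in range(i + 1, 3):
                c = float(np.clip(np.dot(dirs[i], dirs[j]), -1, 1))
                if math.degrees(math.acos(c)) >= 180.0 - collinear_tol_deg:
                    pair = (i, j)
        if pair is None:
            continue
        k = ({0, 1, 2} - set(pair)).pop()
        through = dirs[pair[0]]
        # push opposite the third member, perpendicular to the through-line
        perp = dirs[k] - np.dot(dirs[k], through) * through
        n = np.hypot(*perp)
        if n == 0:  # third edge also collinear: pick either side
            perp = rot90(through)
        else:
            perp = -perp / n
        out.vertices[v] = tuple(p + epsilon * float(np.mean(lens)) * perp)
        moved.append(v)
    if moved:
        try:
            out = rebuild_faces(out)
        except Exception as exc:
            raise RepairError(
                f"T-joint offset of vertices {moved} created a crossing: {exc}"
            ) from exc
        out.metadata["t_joints_repaired"] = moved
    return out


# ---------------------------------------------------------------------------
# convexification


def convexify(
    net: PlanarNetwork,
    max_iter: int = 200,
    tol: float = 1e-9,
    step: float = 0.5,
) -> PlanarNetwork:
    """Nudge reflex vertices until every internal face is convex.

    Reflex vertices (right turns on a CCW loop) are moved toward the
    centroid of their graph neighbours by fraction ``step`` per sweep;
    boundary vertices stay pinned so the silhouette is preserved.
    """
    out = net.copy()
    boundary = set(out.outer_face.loop)
    adj: dict[int, list[int]] = {v: [] for v in out.vertices}
    for e in out.edges:
        adj[e.a].append(e.b)
        adj[e.b].append(e.a)

    total_disp = 0.0
    converged = False
    for it in range(max_iter):
        reflex: set[int] = set()
        for f in out.internal_faces:
            turns = face_turns(out, f)
            bad = np.nonzero(turns <= tol)[0]
            for i in bad:
                reflex.add(f.loop[(i + 1) % len(f.loop)])
        reflex -= boundary
        if not reflex:
            all_ok = all(is_convex_face(out, f, tol) for f in out.internal_faces)
            if all_ok:
                converged = True
                break
            # remaining reflex vertices are pinned boundary ones
            break
        for v in reflex:
            p = out.coords(v)
            target = np.mean([out.coords(w) for w in adj[v]], axis=0)
            newp = p + step * (target - p)
            out.vertices[v] = tuple(newp)
            total_disp += float(np.hypot(*(newp - p)))
        for f in out.internal_faces:
            if out.face_polygon(f).area <= 0:
                raise GeometryError(f"face {f.id} collapsed during convexification")
    out.metadata["convexify_displacement"] = total_disp
    out.metadata["convexify_converged"] = converged or not out.internal_faces
    if total_disp > 0:
        out = rebuild_faces(out)
        out.metadata["convexify_displacement"] = total_disp
        out.metadata["convexify_converged"] = converged
    return out


# ---------------------------------------------------------------------------
# dual topology


def _left_right_faces(net: PlanarNetwork) -> dict[int, tuple[Face | None, Face | None]]:
    """For each edge id, (face left of a->b, face right of a->b)."""
    by_pair: dict[tuple[int, int], Face] = {}
    for f in net.faces:
        loop = f.loop
        for i in range(len(loop)):
            by_pair[(loop[i], loop[(i + 1) % len(loop)])] = f
    out = {}
    for e in net.edges:
        out[e.id] = (by_pair.get((e.a, e.b)), by_pair.get((e.b, e.a)))
    return out


def dual_topology(
    net: PlanarNetwork, require_convex: bool = True, seed: str = "centroid"
) -> ForceDiagram:
    """Build the interior dual graph of a form diagram.

    One dual vertex per internal face, one dual edge per interior form
    edge.  Boundary edges have no dual edge; their forces are handled
    by the virtual boundary loads.  ``seed`` places the starting
    drawing: ``"centroid"`` (default) or ``"circumcenter"``, which for
    a triangulated form is the Voronoi drawing — already exactly
    perpendicular, and the package's canonical force diagram of a
    triangulation.
    """
    if not net.internal_faces:
        raise PreconditionError("network has no internal faces")
    if require_convex:
        bad = [f.id for f in net.internal_faces if not is_convex_face(net, f)]
        if bad:
            raise PreconditionError(f"non-convex internal faces present: {bad}")
    lr = _left_right_faces(net)

    def _place(f: Face):
        if seed == "circumcenter" and len(f.loop) >= 3:
            (ax, ay), (bx, by), (cx, cy) = (net.vertices[v] for v in f.loop[:3])
            d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
            if abs(d) > 1e-30:
                ux = (
                    (ax * ax + ay * ay) * (by - cy)
                    + (bx * bx + by * by) * (cy - ay)
                    + (cx * cx + cy * cy) * (ay - by)
                ) / d
                uy = (
                    (ax * ax + ay * ay) * (cx - bx)
                    + (bx * bx + by * by) * (ax - cx)
                    + (cx * cx + cy * cy) * (bx - ax)
                ) / d
                return (float(ux), float(uy))
        return tuple(np.mean([net.vertices[v] for v in f.loop], axis=0))

    verts = {f.id: _place(f) for f in net.internal_faces}
    dedges = []
    for e in net.edges:
        fl, fr = lr[e.id]
        if fl is None or fr is None or fl.is_outer or fr.is_outer:
            continue
        dedges.append(DualEdge(id=e.id, form_edge_id=e.id, a=fl.id, b=fr.id))
    return ForceDiagram(form=net, vertices=verts, edges=dedges)


# ---------------------------------------------------------------------------
# perpendicularization (form -> force)


def _deviations(force: ForceDiagram) -> dict[int, float]:
    """delta per dual edge: |90 deg - angle(form edge, dual edge)|."""
    out = {}
    for de in force.edges:
        fe = force.form.edge_by_id(de.form_edge_id)
        u = force.form.edge_vector(fe)
        r = force.edge_vector(de)
        nu, nr = np.hypot(*u), np.hypot(*r)
        if nu == 0 or nr < 1e-30:
            out[de.id] = 0.0
            continue
        out[de.id] = math.degrees(math.asin(min(1.0, abs(float(np.dot(u, r))) / (nu * nr))))
    return out


def _assemble_stats(force, iterations, converged, history, tol_deg):
    per = _deviations(force)
    vals = np.array(list(per.values())) if per else np.array([0.0])
    return DeviationStats(
        per_edge_delta=per,
        mean_delta=float(vals.mean()),
        max_delta=float(vals.max()),
        iterations=iterations,
        converged=converged,
        history=history,
    )


def _record_signs(force: ForceDiagram) -> None:
    for de in force.edges:
        fe = force.form.edge_by_id(de.form_edge_id)
        u = force.form.edge_vector(fe)
        s = float(np.dot(force.edge_vector(de), rot90(u)))
        de.sign = 1 if s >= 0 else -1


def _normalize(force: ForceDiagram) -> None:
    lengths = [force.edge_length(de) for de in force.edges]
    longest = max(lengths) if lengths else 0.0
    if longest <= 0:
        return
    factor = force.scale / longest
    c = np.mean([force.coords(v) for v in force.vertices], axis=0)
    for v in force.vertices:
        force.vertices[v] = tuple(c + factor * (force.coords(v) - c))


def perpendicularize(
    form: PlanarNetwork,
    dual: ForceDiagram | None = None,
    tol_deg: float = 0.01,
    max_iter: int = 10000,
    scale: float = 1.0,
    method: str = "iterative",
) -> tuple[ForceDiagram, DeviationStats]:
    """Draw the force diagram so every dual edge is perpendicular to its
    form edge.

    ``method="iterative"`` rotates each dual edge vector onto its target
    direction and re-solves vertex positions (alternating projection);
    ``method="direct"`` projects the initial drawing onto the constraint
    nullspace in closed form, giving a machine-tolerance reciprocal in a
    single step.  The final diagram is scaled so its longest dual edge
    has length ``scale``.
    """
    if dual is None:
        dual = dual_topology(form)
    force = dual.copy()
    force.scale = scale
    vids = sorted(force.vertices)
    if len(vids) <= 1 or not force.edges:
        stats = _assemble_stats(force, 0, True, [], tol_deg)
        _record_signs(force)
        return force, stats
    idx = {v: i for i, v in enumerate(vids)}
    n, m = len(vids), len(force.edges)
    x = np.array([force.vertices[v] for v in vids], dtype=float)

    ia = np.array([idx[de.a] for de in force.edges])
    ib = np.array([idx[de.b] for de in force.edges])
    u = np.array(
        [form.edge_vector(form.edge_by_id(de.form_edge_id)) for de in force.edges],
        dtype=float,
    )
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    # incidence matrix B: edge vectors = B @ positions
    B = sp.coo_matrix(
        (
            np.concatenate([np.ones(m), -np.ones(m)]),
            (np.concatenate([np.arange(m), np.arange(m)]), np.concatenate([ib, ia])),
        ),
        shape=(m, n),
    ).tocsr()

    def write_back(xarr):
        for v, i in idx.items():
            force.vertices[v] = (float(xarr[i, 0]), float(xarr[i, 1]))

    def mean_delta(xarr):
        g = B @ xarr
        ng = np.linalg.norm(g, axis=1)
        dot = np.abs(np.einsum("ij,ij->i", g, u))
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(ng > 1e-30, np.clip(dot / np.maximum(ng, 1e-300), 0, 1), 0.0)
        return float(np.degrees(np.arcsin(s)).mean())

    if method == "direct":
        # project x0 onto {x : (Bx)_e . u_e = 0 for all e}
        C = sp.hstack(
            [B.multiply(u[:, [0]]), B.multiply(u[:, [1]])]
        ).tocsr()  # unknown ordering: all x then all y
        x0 = np.concatenate([x[:, 0], x[:, 1]])
        r = C @ x0
        if C.shape[0] * C.shape[1] <= 4_000_000:
            corr, *_ = np.linalg.lstsq(C.toarray(), r, rcond=None)
        else:
            corr = spla.lsqr(C, r, atol=1e-14, btol=1e-14, iter_lim=20000)[0]
        xs = x0 - corr
        x = np.column_stack([xs[:n], xs[n:]])
        write_back(x)
        stats = _assemble_stats(force, 0, True, [mean_delta(x)], tol_deg)
    elif method == "iterative":
        # prefactor the reduced Laplacian, pinning one vertex per
        # connected component of the dual graph
        parent = list(range(n))

        def _find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in zip(ia, ib):
            parent[_find(int(i))] = _find(int(j))
        pinned = sorted({_find(i) for i in range(n)})
        free = np.array([i for i in range(n) if i not in set(pinned)], dtype=int)
        L = (B.T @ B).tocsc()
        Lff = L[free, :][:, free]
        Lfp = L[free, :][:, pinned].toarray()
        solve = spla.factorized(Lff) if len(free) else None
        history = []
        residuals = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            g = B @ x
            tang = np.einsum("ij,ij->i", g, u)
            residuals.append(float(np.linalg.norm(tang)))
            rho = g - tang[:, None] * u  # rotate each edge onto its target
            rhs = B.T @ rho
            if solve is not None:
                for k in (0, 1):
                    x[free, k] = solve(rhs[free, k] - Lfp @ x[pinned, k])
            d = mean_delta(x)
            history.append(d)
            if d <= tol_deg:
                converged = True
                break
        write_back(x)
        stats = _assemble_stats(force, it, converged, history, tol_deg)
        stats.residual_history = residuals
    else:
        raise ValueError(f"unknown method {method!r}")

    _record_signs(force)
    _normalize(force)
    stats_final = _assemble_stats(force, stats.iterations, stats.converged, stats.history, tol_deg)
    stats_final.residual_history = stats.residual_history
    return force, stats_final


# ---------------------------------------------------------------------------
# GDoF


def gdof_matrix(net: PlanarNetwork) -> tuple[np.ndarray, list[int]]:
    """Closure system of the dual: one scalar per edge, closure per face.

    Unknown ``q_e`` is the signed length of the dual edge of form edge
    ``e`` along its fixed perpendicular direction.  For every internal
    form face the duals of its boundary edges must close; rotating the
    whole equation by 90 degrees this reads ``sum_e q_e sigma_{f,e}
    u_e = 0`` with ``u_e`` the unit form edge direction and ``sigma``
    the traversal orientation.
    """
    if not net.internal_faces:
        raise PreconditionError("gdof of an empty internal network is undefined")
    eids = [e.id for e in net.edges]
    col = {eid: i for i, eid in enumerate(eids)}
    by_pair = {frozenset((e.a, e.b)): e for e in net.edges}
    rows = []
    for f in net.internal_faces:
        loop = f.loop
        rx = np.zeros(len(eids))
        ry = np.zeros(len(eids))
        for i in range(len(loop)):
            a, b = loop[i], loop[(i + 1) % len(loop)]
            e = by_pair[frozenset((a, b))]
            u = net.edge_vector(e)
            u = u / np.hypot(*u)
            sigma = 1.0 if (e.a, e.b) == (a, b) else -1.0
            rx[col[e.id]] += sigma * u[0]
            ry[col[e.id]] += sigma * u[1]
        rows.append(rx)
        rows.append(ry)
    return np.array(rows), eids


def gdof(net: PlanarNetwork, rank_tol: float = 1e-8) -> int:
    """Geometric degrees of freedom of the force diagram.

    The numeric nullity of the dual closure system: 1 means the force
    diagram is unique up to scale, i.e. the form is statically
    determinate.
    """
    A, eids = gdof_matrix(net)
    sv = np.linalg.svd(A, compute_uv=False)
    smax = sv[0] if len(sv) else 0.0
    rank = int(np.sum(sv > rank_tol * smax)) if smax > 0 else 0
    return len(eids) - rank


# ---------------------------------------------------------------------------
# reconstruction (force -> form)


def consistent_anchors(
    force: ForceDiagram, target_edge_lengths: dict[int, float], n: int = 2
) -> dict[int, tuple[float, float]]:
    """Anchor positions consistent with the target lengths.

    Solves the reconstruction once with a single vertex pinned at the
    origin and returns the ``n`` mutually most distant solved positions,
    so they can be passed to :func:`reconstruct_form` without fighting
    the least-squares fit.
    """
    vids = sorted(force.form.vertices)
    net, _ = reconstruct_form(
        force,
        target_edge_lengths,
        {vids[0]: (0.0, 0.0)},
        _min_anchors=1,
    )
    pts = {v: np.asarray(net.vertices[v]) for v in vids}
    a = vids[0]
    b = max(vids, key=lambda v: np.linalg.norm(pts[v] - pts[a]))
    chosen = [a, b]
    while len(chosen) < min(n, len(vids)):
        c = max(
            vids,
            key=lambda v: min(np.linalg.norm(pts[v] - pts[w]) for w in chosen),
        )
        chosen.append(c)
    return {v: tuple(map(float, pts[v])) for v in chosen}


def reconstruct_form(
    force: ForceDiagram,
    target_edge_lengths: dict[int, float],
    anchor_vertices: dict[int, tuple[float, float]],
    tol_deg: float = 0.01,
    max_iter: int = 10000,
    direction_weight: float = 1.0,
    proximity: tuple[float, dict[int, tuple[float, float]]] | None = None,
    _min_anchors: int = 2,
) -> tuple[PlanarNetwork, DeviationStats]:
    """Solve form vertex positions from a converged force diagram.

    Every interior form edge must be perpendicular to its dual edge and
    match its target length; the resulting linear system is solved in
    least squares with the anchors eliminated.  ``target_edge_lengths``
    maps form edge ids to positive lengths.  ``direction_weight``
    up-weights the perpendicularity residual relative to the length
    residual: with a large weight, inconsistent target lengths (e.g.
    learned predictions) are projected onto the consistent reciprocal
    family instead of folding the drawing.  ``proximity = (weight,
    positions)`` adds a Tikhonov pull of every free vertex toward a
    reference drawing (a trust region around a known-planar solution).
    """
    form = force.form
    if len(anchor_vertices) < _min_anchors:
        raise PreconditionError("at least 2 anchor vertices are required")
    missing = [de.form_edge_id for de in force.edges if de.form_edge_id not in target_edge_lengths]
    if missing:
        raise PreconditionError(f"missing target lengths for edges {missing}")

    vids = sorted(form.vertices)
    idx = {v: i for i, v in enumerate(vids)}
    free = [v for v in vids if v not in anchor_vertices]
    touched = set(anchor_vertices)
    for de in force.edges:
        fe = form.edge_by_id(de.form_edge_id)
        touched.add(fe.a)
        touched.add(fe.b)
    dangling = [v for v in vids if v not in touched]
    if dangling:
        raise PreconditionError(
            f"vertices {dangling} have no interior edge and are not anchored"
        )

    fidx = {v: i for i, v in enumerate(free)}
    # per edge, two scalar rows in the (tangent, normal) frame of the
    # target direction: tangential component = target length (weight 1),
    # normal component = 0 (weight direction_weight)
    rows_i, rows_j, vals = [], [], []
    rhs = []
    nrow = 0
    for de in force.edges:
        fe = form.edge_by_id(de.form_edge_id)
        rho = force.edge_vector(de)
        nr = np.hypot(*rho)
        if nr < 1e-30:
            continue  # zero-force member constrains direction not at all
        that = de.sign * np.array([rho[1], -rho[0]]) / nr  # R(-90) of rho
        nhat = np.array([-that[1], that[0]])
        for direction, weight, target in (
            (that, 1.0, float(target_edge_lengths[de.form_edge_id])),
            (nhat, direction_weight, 0.0),
        ):
            b_val = weight * target
            for v, s in ((fe.b, 1.0), (fe.a, -1.0)):
                contrib = s * weight * direction
                if v in fidx:
                    rows_i.extend([nrow, nrow])
                    rows_j.extend([2 * fidx[v], 2 * fidx[v] + 1])
                    vals.extend([contrib[0], contrib[1]])
                else:
                    b_val -= float(
                        np.dot(contrib, np.asarray(anchor_vertices[v], dtype=float))
                    )
            rhs.append(b_val)
            nrow += 1
    if proximity is not None:
        w_prox, ref = proximity
        if w_prox > 0:
            for v in free:
                for k in (0, 1):
                    rows_i.append(nrow)
                    rows_j.append(2 * fidx[v] + k)
                    vals.append(w_prox)
                    rhs.append(w_prox * float(ref[v][k]))
                    nrow += 1
    A = sp.coo_matrix((vals, (rows_i, rows_j)), shape=(nrow, 2 * len(free))).tocsr()
    rhs = np.asarray(rhs)
    X = np.zeros(2 * len(free))
    if len(free):
        AtA = (A.T @ A).tocsc()
        solve = spla.factorized(AtA)
        X = solve(A.T @ rhs)

    coords = {}
    for v in vids:
        if v in anchor_vertices:
            coords[v] = tuple(np.asarray(anchor_vertices[v], dtype=float))
        else:
            coords[v] = (float(X[2 * fidx[v]]), float(X[2 * fidx[v] + 1]))

    edges = [Edge(e.id, e.a, e.b, e.width, e.boundary) for e in form.edges]
    try:
        net = build_faces(coords, edges, metadata=dict(form.metadata))
        net.metadata["embedding_valid"] = True
    except Exception:
        net = PlanarNetwork(
            vertices=coords,
            edges=edges,
            faces=[Face(f.id, list(f.loop), f.is_outer) for f in form.faces],
            metadata=dict(form.metadata),
        )
        net.metadata["embedding_valid"] = False

    # deviation of the reconstructed form edges from perpendicularity
    # (from the solved coordinates: vertex merging in face extraction
    # may have contracted degenerate edges of the returned network)
    edge_by_id = {e.id: e for e in form.edges}
    per = {}
    for de in force.edges:
        fe = edge_by_id[de.form_edge_id]
        u = np.asarray(coords[fe.b]) - np.asarray(coords[fe.a])
        rho = force.edge_vector(de)
        nu, nr = np.hypot(*u), np.hypot(*rho)
        if nu < 1e-30 or nr < 1e-30:
            per[de.form_edge_id] = 0.0
            continue
        per[de.form_edge_id] = math.degrees(
            math.asin(min(1.0, abs(float(np.dot(u, rho))) / (nu * nr)))
        )
    vals_ = np.array(list(per.values())) if per else np.array([0.0])
    stats = DeviationStats(
        per_edge_delta=per,
        mean_delta=float(vals_.mean()),
        max_delta=float(vals_.max()),
        iterations=1,
        converged=bool(vals_.mean() <= tol_deg),
    )
    return net, stats


# ---------------------------------------------------------------------------
# equilibrium check


def node_closure_residuals(form: PlanarNetwork, force: ForceDiagram) -> dict[int, float]:
    """Force-polygon closure residual at every internal form vertex.

    Walking the faces around an internal vertex, each dual edge rotated
    by -90 degrees is (for an exact reciprocal) the force carried by the
    corresponding member along its axis; projecting onto the member
    directions and summing measures how far the node is from
    equilibrium.  Residuals are absolute, in force (dual length) units.
    """
    lr = _left_right_faces(form)
    inc = form.vertex_edges()
    out = {}
    for v in form.internal_vertices():
        p = form.coords(v)
        total = np.zeros(2)
        for e in inc[v]:
            fl, fr = lr[e.id]
            if fl is None or fr is None or fl.is_outer or fr.is_outer:
                continue
            rho = force.coords(fr.id) - force.coords(fl.id)
            t = np.array([rho[1], -rho[0]])  # R(-90)
            w = e.b if e.a == v else e.a
            d = form.coords(w) - p
            d = d / np.hypot(*d)
            if (e.a, e.b) != (v, w):
                t = -t
            total += np.dot(t, d) * d
        out[v] = float(np.hypot(*total))
    return out
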