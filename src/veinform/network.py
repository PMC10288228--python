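"""Planar embedded graph model for form and force diagrams.

A :class:`PlanarNetwork` stores a straight-line planar embedding of a
vein network: vertices with coordinates (y-up mathematical convention),
edges with optional measured widths, and the faces of the embedding.
Faces are recovered from the embedding by leftmost-turn traversal of
directed edges; internal faces are oriented counter-clockwise and the
single outer face clockwise, so signed (shoelace) areas are sign-stable
invariants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Polygon
from shapely.strtree import STRtree

from .errors import (
    ConnectivityError,
    EmbeddingError,
    GeometryError,
    PreconditionError,
)

#: vertices closer than this fraction of the bounding-box diagonal are merged
MERGE_TOL_FRACTION = 1e-6


@dataclass
class Edge:
    """An undirected edge between vertex ids ``a`` and ``b``."""

    id: int
    a: int
    b: int
    width: float | None = None
    boundary: bool = False


@dataclass
class Face:
    """A simple closed loop of vertex ids bounding one face."""

    id: int
    loop: list[int]
    is_outer: bool = False


@dataclass
class FaceMetrics:
    """Morphometrics of one internal cell."""

    face_id: int
    area: float
    perimeter: float
    circularity: float


@dataclass
class PlanarNetwork:
    """A planar embedded vein network (form or force geometry)."""

    vertices: dict[int, tuple[float, float]]
    edges: list[Edge]
    faces: list[Face] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    # -- basic accessors -------------------------------------------------
    def coords(self, vid: int) -> np.ndarray:
        return np.asarray(self.vertices[vid], dtype=float)

    def edge_by_id(self, eid: int) -> Edge:
        for e in self.edges:
            if e.id == eid:
                return e
        raise KeyError(eid)

    def edge_vector(self, edge: Edge) -> np.ndarray:
        return self.coords(edge.b) - self.coords(edge.a)

    def edge_length(self, edge: Edge) -> float:
        return float(np.hypot(*self.edge_vector(edge)))

    @property
    def internal_faces(self) -> list[Face]:
        return [f for f in self.faces if not f.is_outer]

    @property
    def outer_face(self) -> Face:
        for f in self.faces:
            if f.is_outer:
                return f
        raise PreconditionError("faces not built: no outer face present")

    def face_polygon(self, face: Face) -> Polygon:
        return Polygon([self.vertices[v] for v in face.loop])

    def bbox_diagonal(self) -> float:
        pts = np.array(list(self.vertices.values()), dtype=float)
        span = pts.max(axis=0) - pts.min(axis=0)
        return float(np.hypot(*span))

    # -- incidence maps --------------------------------------------------
    def vertex_edges(self) -> dict[int, list[Edge]]:
        inc: dict[int, list[Edge]] = {v: [] for v in self.vertices}
        for e in self.edges:
            inc[e.a].append(e)
            inc[e.b].append(e)
        return inc

    def edge_face_map(self) -> dict[int, list[Face]]:
        """Map edge id -> faces whose loop traverses that edge."""
        by_pair: dict[frozenset, int] = {
            frozenset((e.a, e.b)): e.id for e in self.edges
        }
        out: dict[int, list[Face]] = {e.id: [] for e in self.edges}
        for f in self.faces:
            loop = f.loop
            for i in range(len(loop)):
                key = frozenset((loop[i], loop[(i + 1) % len(loop)]))
                out[by_pair[key]].append(f)
        return out

    def interior_edges(self) -> list[Edge]:
        """Edges shared by two internal faces."""
        efm = self.edge_face_map()
        return [
            e
            for e in self.edges
            if sum(1 for f in efm[e.id] if not f.is_outer) == 2
        ]

    def internal_vertices(self) -> list[int]:
        """Vertices not on the outer face loop."""
        outer = set(self.outer_face.loop)
        return [v for v in self.vertices if v not in outer]

    # -- copying ---------------------------------------------------------
    def copy(self) -> "PlanarNetwork":
        return PlanarNetwork(
            vertices={v: tuple(p) for v, p in self.vertices.items()},
            edges=[Edge(e.id, e.a, e.b, e.width, e.boundary) for e in self.edges],
            faces=[Face(f.id, list(f.loop), f.is_outer) for f in self.faces],
            metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# construction


def _merge_close_vertices(vertices, edges, tol):
    """Merge vertices closer than ``tol``; drop collapsed/duplicate edges."""
    ids = list(vertices)
    pts = np.array([vertices[v] for v in ids], dtype=float)
    parent = {v: v for v in ids}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    if len(ids) > 1 and tol > 0:
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        for i, j in tree.query_pairs(tol):
            parent[find(ids[max(i, j)])] = find(ids[min(i, j)])

    merged_vertices = {}
    for v in ids:
        r = find(v)
        if r not in merged_vertices:
            merged_vertices[r] = vertices[r]
    merged_edges, seen = [], set()
    for e in edges:
        a, b = find(e.a), find(e.b)
        if a == b:
            continue
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        merged_edges.append(Edge(e.id, a, b, e.width, e.boundary))
    return merged_vertices, merged_edges


def _check_planarity(vertices, edges):
    segs = [
        LineString([vertices[e.a], vertices[e.b]]) for e in edges
    ]
    tree = STRtree(segs)
    for i, (e, s) in enumerate(zip(edges, segs)):
        for j in tree.query(s):
            j = int(j)
            if j <= i:
                continue
            o = edges[j]
            if {e.a, e.b} & {o.a, o.b}:
                continue  # shared endpoint is allowed
            if s.intersects(segs[j]):
                raise EmbeddingError(
                    f"edges {e.id} and {o.id} cross away from their endpoints"
                )


def _check_connected(vertices, edges):
    if not vertices:
        raise PreconditionError("empty vertex set")
    adj: dict[int, list[int]] = {v: [] for v in vertices}
    for e in edges:
        adj[e.a].append(e.b)
        adj[e.b].append(e.a)
    start = next(iter(vertices))
    seen = {start}
    stack = [start]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    if len(seen) != len(vertices):
        raise ConnectivityError(
            f"graph is disconnected: reached {len(seen)} of {len(vertices)} vertices"
        )


def build_faces(
    vertices: dict[int, tuple[float, float]],
    edges: list[Edge],
    metadata: dict | None = None,
    merge_tol: float | None = None,
) -> PlanarNetwork:
    """Extract all faces of a connected planar straight-line embedding.

    Directed edges are traversed by the leftmost-turn rule (at each
    vertex continue along the incident edge that makes the sharpest
    counter-clockwise turn), which partitions the directed edges into
    face loops.  The loop of most negative signed area is the outer
    face.  Raises :class:`EmbeddingError` on crossing edges and
    :class:`ConnectivityError` on disconnected input.
    """
    vertices = {v: (float(x), float(y)) for v, (x, y) in vertices.items()}
    for v, (x, y) in vertices.items():
        if not (math.isfinite(x) and math.isfinite(y)):
            raise PreconditionError(f"vertex {v} has non-finite coordinates")
    if merge_tol is None:
        pts = np.array(list(vertices.values()), dtype=float)
        diag = float(np.hypot(*(pts.max(axis=0) - pts.min(axis=0)))) if len(pts) > 1 else 0.0
        merge_tol = MERGE_TOL_FRACTION * diag
    vertices, edges = _merge_close_vertices(vertices, edges, merge_tol)
    _check_connected(vertices, edges)
    _check_planarity(vertices, edges)

    # neighbours of each vertex sorted by direction angle (CCW order)
    nbrs: dict[int, list[int]] = {v: [] for v in vertices}
    for e in edges:
        nbrs[e.a].append(e.b)
        nbrs[e.b].append(e.a)
    angle_of: dict[tuple[int, int], float] = {}
    for v, ns in nbrs.items():
        p = np.asarray(vertices[v])
        for w in ns:
            d = np.asarray(vertices[w]) - p
            angle_of[(v, w)] = math.atan2(d[1], d[0])
        ns.sort(key=lambda w: angle_of[(v, w)])

    def next_half_edge(u, v):
        # at v, coming from u: continue with the neighbour that follows
        # the reversed direction v->u in clockwise order (leftmost turn)
        ns = nbrs[v]
        i = ns.index(u)
        return v, ns[i - 1]

    remaining = {(e.a, e.b) for e in edges} | {(e.b, e.a) for e in edges}
    loops: list[list[int]] = []
    while remaining:
        u0, v0 = min(remaining)
        loop = [u0]
        u, v = u0, v0
        while True:
            remaining.discard((u, v))
            loop.append(v)
            u, v = next_half_edge(u, v)
            if (loop[0], loop[1]) == (u, v):
                break
        loops.append(loop[:-1])

    def signed_area(loop):
        p = np.array([vertices[v] for v in loop], dtype=float)
        x, y = p[:, 0], p[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    areas = [signed_area(lp) for lp in loops]
    outer_idx = int(np.argmin(areas))
    faces = []
    for i, (lp, a) in enumerate(zip(loops, areas)):
        is_outer = i == outer_idx
        if not is_outer and a <= 0:
            raise GeometryError(
                f"face loop {lp} has non-positive area {a}; degenerate embedding"
            )
        faces.append(Face(id=i, loop=lp, is_outer=is_outer))

    net = PlanarNetwork(
        vertices=vertices,
        edges=edges,
        faces=faces,
        metadata=dict(metadata or {}),
    )
    # Euler relation, counting the outer face
    v_n, e_n, f_n = len(net.vertices), len(net.edges), len(net.faces)
    if v_n - e_n + f_n != 2:
        raise EmbeddingError(
            f"Euler relation violated: V-E+F = {v_n}-{e_n}+{f_n} != 2"
        )
    efm = net.edge_face_map()
    for e in net.edges:
        e.boundary = any(f.is_outer for f in efm[e.id])
    return net


def rebuild_faces(net: PlanarNetwork) -> PlanarNetwork:
    """Re-run face extraction on a network's own vertices and edges."""
    return build_faces(net.vertices, net.edges, metadata=net.metadata)


# ---------------------------------------------------------------------------
# morphometrics


def face_metrics(net: PlanarNetwork) -> list[FaceMetrics]:
    """Shoelace area, perimeter and circularity of every internal cell.

    Circularity is ``4*pi*area / perimeter**2``: the ratio of the cell
    area to the area of a circle with the same perimeter (1 for a disc).
    """
    out = []
    for f in net.internal_faces:
        poly = net.face_polygon(f)
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(f"face {f.id} is self-intersecting or degenerate")
        area = poly.area
        perim = poly.length
        out.append(
            FaceMetrics(
                face_id=f.id,
                area=float(area),
                perimeter=float(perim),
                circularity=float(4.0 * math.pi * area / perim**2),
            )
        )
    return out


def count_vef(net: PlanarNetwork) -> tuple[int, int, int]:
    """(n_vertices, n_edges, n_internal_faces) of the network."""
    return len(net.vertices), len(net.edges), len(net.internal_faces)


# ---------------------------------------------------------------------------
# JSON schema


def to_json_dict(net: PlanarNetwork) -> dict:
    return {
        "units": net.metadata.get("units", "px"),
        "metadata": {k: v for k, v in net.metadata.items() if k != "units"},
        "vertices": [
            {"id": v, "x": x, "y": y} for v, (x, y) in sorted(net.vertices.items())
        ],
        "edges": [
            {"id": e.id, "v": [e.a, e.b], "width": e.width, "boundary": e.boundary}
            for e in net.edges
        ],
        "faces": [
            {"id": f.id, "loop": f.loop, "outer": f.is_outer} for f in net.faces
        ],
    }


def from_json_dict(data: dict) -> PlanarNetwork:
    vertices = {int(v["id"]): (float(v["x"]), float(v["y"])) for v in data["vertices"]}
    edges = [
        Edge(
            id=int(e["id"]),
            a=int(e["v"][0]),
            b=int(e["v"][1]),
            width=None if e.get("width") is None else float(e["width"]),
        )
        for e in data["edges"]
    ]
    metadata = dict(data.get("metadata", {}))
    metadata["units"] = data.get("units", "px")
    # faces are always recomputed: they are derivable and this keeps the
    # loader robust to hand-edited files
    return build_faces(vertices, edges, metadata=metadata)


def save_network(net: PlanarNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(to_json_dict(net), fh, indent=1, sort_keys=True)


def load_network(path) -> PlanarNetwork:
    with open(path) as fh:
        return from_json_dict(json.load(fh))
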