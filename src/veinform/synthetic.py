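"""Seeded generator of wing-like statically determinate networks.

The generator emulates the structural signature of a dragonfly wing's
main network: a convex, elongated outline; a row of wide, shallow cells
along the leading edge carrying the primary load path; and a finer
triangulated mesh filling the rest of the blade, graded coarser toward
the trailing edge.  All internal faces are convex triangles, the dual
closure system has nullity one (static determinacy), and member widths
are planted in strict proportion to the dual forces, optionally with
multiplicative log-normal noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon

from .errors import GeometryError, SpecError
from .network import Edge, PlanarNetwork, build_faces
from .reciprocal import ForceDiagram, dual_topology, perpendicularize
from .sizing import size_members


@dataclass
class WingSpec:
    """Parameters of one synthetic wing."""

    n_cells: int = 50
    chord: float = 4.0
    depth: float = 1.0
    waypoints: int | None = None  # primary-path columns; default ~n_cells/12
    density_level: int = 1      # 0 (coarse) .. 3 (fine) secondary-mesh density
    noise: float = 0.0          # sigma of multiplicative log-normal width noise
    d_max: float = 60.0         # thickest member diameter, px
    seed: int = 0

    @property
    def n_waypoints(self) -> int:
        if self.waypoints is not None:
            return self.waypoints
        return max(2, self.n_cells // 12)


# ---------------------------------------------------------------------------
# outline


def _outline_curves(spec: WingSpec):
    """Top (leading) and bottom (trailing) outline curves, y-up."""
    cap = 0.3 * spec.depth

    def y_top(t):
        return 0.16 * spec.depth * np.sin(math.pi * np.asarray(t, dtype=float))

    def y_bot(t):
        t = np.asarray(t, dtype=float)
        return -(cap + (spec.depth - cap) * np.sin(math.pi * t) ** 0.9)

    return y_top, y_bot, cap


def boundary_polygon(spec: WingSpec, n_bottom: int = 60) -> Polygon:
    """Smooth closed outline used for containment tests and rendering."""
    y_top, y_bot, _ = _outline_curves(spec)
    t = np.linspace(0, 1, 80)
    top = np.column_stack([t * spec.chord, y_top(t)])
    t2 = np.linspace(1, 0, n_bottom)
    bot = np.column_stack([t2 * spec.chord, y_bot(t2)])
    return Polygon(np.vstack([top, bot]))


# ---------------------------------------------------------------------------
# point placement


def _band_depth(spec: WingSpec, t):
    """Depth of the primary band below the leading edge.

    The band cells are wide and shallow (the long narrow cells between
    the longitudinal veins of a real wing); the shallowest point sits at
    mid-chord so the primary load path peaks there and tapers toward the
    tips.
    """
    delta = spec.chord / spec.n_waypoints
    t = np.asarray(t, dtype=float)
    return delta * (0.06 + 0.09 * np.abs(2 * t - 1) ** 1.2)


def _place_points(spec: WingSpec, rng: np.random.Generator, h: float):
    """Boundary and interior seed points for one wing."""
    y_top, y_bot, cap = _outline_curves(spec)
    c = spec.chord
    W = spec.n_waypoints
    delta = c / W
    # leading edge: coarse waypoints (primary band columns)
    tt = np.linspace(0, 1, W + 1)
    top_pts = np.column_stack([tt * c, y_top(tt)])
    # trailing edge: sampled near the fine spacing
    n_bot = max(4, int(round(1.15 * c / h)))
    tb = np.linspace(0, 1, n_bot + 1)[1:-1]
    bot_pts = np.column_stack([tb * c, y_bot(tb)])
    # blunt end caps
    cap_pts = np.array([[0.0, float(y_bot(0.0))], [c, float(y_bot(1.0))]])
    boundary = np.vstack([top_pts, bot_pts, cap_pts])

    # primary band row: staggered shallow row just below the leading edge
    xb = (np.arange(W) + 0.5) * delta
    tband = xb / c
    band = np.column_stack([xb, y_top(tband) - _band_depth(spec, tband)])

    # secondary mesh: jittered hex lattice between band row and outline
    rows = []
    row_h = 0.87 * h
    n_rows = int(math.ceil(2.2 * spec.depth / row_h)) + 2
    for k in range(n_rows):
        y0 = -0.75 * h - k * row_h
        xs = np.arange((0.55 + 0.5 * (k % 2)) * h, c - 0.5 * h, h)
        if not len(xs):
            continue
        xs = xs + rng.uniform(-0.18, 0.18, len(xs)) * h
        ys = (
            y_top(xs / c)
            - _band_depth(spec, xs / c)
            + y0
            + rng.uniform(-0.18, 0.18, len(xs)) * h
        )
        keep = ys > y_bot(xs / c) + 0.6 * h
        rows.append(np.column_stack([xs[keep], ys[keep]]))
    interior = np.vstack([band] + rows) if rows else band
    return boundary, interior


def _triangulate(boundary, interior, poly):
    pts = np.vstack([boundary, interior])
    # drop near-duplicates to keep Delaunay well conditioned
    keep = np.ones(len(pts), bool)
    from scipy.spatial import cKDTree

    tree = cKDTree(pts)
    for i, j in sorted(tree.query_pairs(1e-6)):
        keep[max(i, j)] = False
    pts = pts[keep]
    tri = Delaunay(pts)
    cent = pts[tri.simplices].mean(axis=1)
    inside = np.array([poly.contains(Point(p)) for p in cent])
    simplices = tri.simplices[inside]
    edges = set()
    for s in simplices:
        for i in range(3):
            edges.add(frozenset((int(s[i]), int(s[(i + 1) % 3]))))
    return pts, simplices, edges


def _build_network(pts, edges, metadata):
    vertices = {i: (float(p[0]), float(p[1])) for i, p in enumerate(pts)}
    used = sorted({v for e in edges for v in e})
    vertices = {v: vertices[v] for v in used}
    edge_objs = [
        Edge(i, *sorted(e)) for i, e in enumerate(sorted(edges, key=sorted))
    ]
    return build_faces(vertices, edge_objs, metadata=metadata)


def _lonely_vertices(net: PlanarNetwork) -> list[int]:
    """Vertices with no incident interior edge (cannot be dual-placed)."""
    interior_eids = {e.id for e in net.interior_edges()}
    inc = net.vertex_edges()
    return sorted(
        v for v, es in inc.items() if not any(e.id in interior_eids for e in es)
    )


def _circumcenter(p1, p2, p3) -> tuple[float, float]:
    (ax, ay), (bx, by), (cx, cy) = p1, p2, p3
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
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


def primary_path_stats(net: PlanarNetwork, forces: dict[int, float]) -> dict:
    """Connectivity and chord span of the top-decile-force subgraph."""
    eids = sorted(forces, key=forces.get, reverse=True)
    n_top = max(1, int(math.ceil(len(eids) / 10)))
    top = eids[:n_top]
    by_id = {e.id: e for e in net.edges}
    parent: dict[int, int] = {}

    def find(v):
        parent.setdefault(v, v)
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for eid in top:
        e = by_id[eid]
        parent[find(e.a)] = find(e.b)
    comps: dict[int, list[int]] = {}
    for eid in top:
        e = by_id[eid]
        comps.setdefault(find(e.a), []).append(eid)
    best = max(comps.values(), key=len)
    xs = [net.coords(v)[0] for eid in best for v in (by_id[eid].a, by_id[eid].b)]
    all_x = np.array([p[0] for p in net.vertices.values()])
    span = (max(xs) - min(xs)) / float(all_x.max() - all_x.min())
    return {
        "n_top": n_top,
        "n_components": len(comps),
        "largest_component_edges": len(best),
        "span_fraction": float(span),
    }


def generate_wing(
    spec: WingSpec,
) -> tuple[PlanarNetwork, ForceDiagram, dict[int, float]]:
    """Generate one wing: network, exact reciprocal, planted widths.

    The triangle count is adjusted to exactly ``spec.n_cells`` internal
    faces by adding or removing fine-mesh points.  Widths are planted as
    ``d = k * F`` from the machine-tolerance reciprocal; ``spec.noise``
    applies multiplicative log-normal noise on top.  The jitter draw is
    re-derived deterministically from the seed until the generated wing
    satisfies its primary-path postcondition (top-decile-force edges
    connected across >= 60% of the chord), so equal specs always yield
    byte-identical output.
    """
    if spec.n_cells < 1:
        raise SpecError("n_cells must be >= 1")
    last = None
    for attempt in range(8):
        rng = np.random.default_rng((spec.seed + 1_000_003 * attempt) % 2**31)
        try:
            net, force, widths = _generate_wing_attempt(spec, rng)
        except SpecError as exc:
            last = exc
            continue
        if net.metadata["primary_path"]["span_fraction"] >= 0.6:
            return net, force, widths
        last = SpecError(
            f"primary path spans {net.metadata['primary_path']['span_fraction']:.2f}"
        )
    raise SpecError(f"no valid wing for spec {spec}: {last}")


def _generate_wing_attempt(
    spec: WingSpec, rng: np.random.Generator
) -> tuple[PlanarNetwork, ForceDiagram, dict[int, float]]:
    poly = boundary_polygon(spec)
    if not poly.is_valid:
        raise SpecError("outline curves self-intersect")
    area = poly.area
    W = spec.n_waypoints
    # initial fine spacing from the target cell budget
    h = math.sqrt(2.3 * area / max(spec.n_cells - 2 * W, 8))
    h *= (0.88) ** (spec.density_level - 1)

    boundary, interior = _place_points(spec, rng, h)
    y_bot = _outline_curves(spec)[1]
    extra_tb: list[float] = []
    meta = {"units": "model", "source": f"synthetic:seed={spec.seed}", "seed": spec.seed}

    def attempt(interior_pts):
        extra = (
            np.column_stack([np.array(extra_tb) * spec.chord, y_bot(extra_tb)])
            if extra_tb
            else np.empty((0, 2))
        )
        pts, simplices, edges = _triangulate(
            np.vstack([boundary, extra]), interior_pts, poly
        )
        net = _build_network(pts, edges, dict(meta))
        return net, pts

    net, pts = attempt(interior)
    for _ in range(600):
        diff = len(net.internal_faces) - spec.n_cells
        lonely = _lonely_vertices(net)
        if diff == 0 and not lonely:
            break
        if lonely:
            # a vertex with no interior edge cannot be reconstructed from
            # the dual; seed a point inside its star to connect it
            inc = net.vertex_edges()
            v = lonely[0]
            star = [w for e in inc[v] for w in (e.a, e.b) if w != v]
            target = np.mean([net.coords(w) for w in star] + [net.coords(v)] * 2, axis=0)
            interior = np.vstack([interior, target])
        elif diff % 2 != 0:
            # odd mismatch: adding a point on the convex outline adds one face
            tbs = sorted(
                [0.0, 1.0]
                + list(extra_tb)
                + list(np.linspace(0, 1, max(4, int(round(1.15 * spec.chord / h))) + 1)[1:-1])
            )
            gaps = np.diff(tbs)
            g = int(np.argmax(gaps))
            extra_tb.append(float((tbs[g] + tbs[g + 1]) / 2))
        elif diff > 0:
            fine = interior[W:]
            if not len(fine):
                raise SpecError("cannot reduce cells below the primary band")
            drop = W + int(np.argmin(fine[:, 1]))
            interior = np.delete(interior, drop, axis=0)
        else:
            for _ in range(100):
                cand = np.array(
                    [rng.uniform(0, spec.chord), rng.uniform(-spec.depth, 0.0)]
                )
                if poly.contains(Point(cand)) and np.min(
                    np.linalg.norm(interior - cand, axis=1)
                ) > 0.5 * h:
                    interior = np.vstack([interior, cand])
                    break
            else:
                raise SpecError("could not place an additional interior point")
        net, pts = attempt(interior)
    else:
        raise SpecError(
            f"failed to reach exactly {spec.n_cells} cells (got {len(net.internal_faces)})"
        )

    # the canonical reciprocal of a triangulated form: start the dual at
    # the circumcenters (the orthogonal/Voronoi dual is exactly
    # perpendicular) and project, which leaves it untouched up to float
    dual = dual_topology(net)
    for f in net.internal_faces:
        dual.vertices[f.id] = _circumcenter(*[net.vertices[v] for v in f.loop])
    force, stats = perpendicularize(net, dual, method="direct")
    if stats.mean_delta > 1e-6:
        raise GeometryError(
            f"exact reciprocal not reached (mean delta {stats.mean_delta} deg)"
        )
    sizing = size_members(force, d_max=spec.d_max)
    widths = dict(sizing.diameter)
    # boundary members: the costa (leading edge) is the thickest vein,
    # tapering toward the trailing edge
    y_top_f, y_bot_f, _ = _outline_curves(spec)
    for e in net.edges:
        if e.boundary:
            mid = (net.coords(e.a) + net.coords(e.b)) / 2
            t = float(np.clip(mid[0] / spec.chord, 0, 1))
            rel_depth = float(
                (y_top_f(t) - mid[1]) / max(y_top_f(t) - y_bot_f(t), 1e-9)
            )
            widths[e.id] = spec.d_max * (0.35 + 0.55 * math.exp(-4.0 * rel_depth))
    if spec.noise > 0:
        for eid in sorted(widths):
            widths[eid] *= float(np.exp(spec.noise * rng.standard_normal()))
    for e in net.edges:
        if e.id in widths:
            e.width = widths[e.id]
    net.metadata["n_cells"] = len(net.internal_faces)
    net.metadata["primary_path"] = primary_path_stats(net, sizing.force)
    return net, force, widths


def lens_mesh(
    n_rows: int = 5, seed: int = 0, chord: float = 4.0, depth: float = 1.4
) -> PlanarNetwork:
    """A well-conditioned triangulated lens (no primary band).

    Jittered hex-lattice interior points inside a blunt lens outline
    give Delaunay triangles with no acute wedges, which is the fixture
    of choice for render -> vectorize round trips (very shallow
    junction angles, as in the primary band, cannot be resolved
    exactly by any skeleton-based tracer at realistic stroke widths).
    """
    rng = np.random.default_rng(seed)
    spec = WingSpec(chord=chord, depth=depth, waypoints=2)
    y_top, y_bot, _ = _outline_curves(spec)
    h = depth / (n_rows - 1.0)
    tb = np.linspace(0, 1, max(4, int(round(1.1 * chord / h))) + 1)
    top = np.column_stack([tb * chord, y_top(tb)])
    bot = np.column_stack([tb[1:-1] * chord, y_bot(tb[1:-1])])
    caps = np.array([[0.0, float(y_bot(0.0))], [chord, float(y_bot(1.0))]])
    boundary = np.vstack([top, bot, caps])
    rows = []
    for k in range(1, 2 * n_rows):
        y0 = -0.8 * h * k + 0.05 * depth
        xs = np.arange((0.6 + 0.5 * (k % 2)) * h, chord - 0.5 * h, h)
        if not len(xs):
            continue
        xs = xs + rng.uniform(-0.15, 0.15, len(xs)) * h
        ys = y0 + rng.uniform(-0.15, 0.15, len(xs)) * h
        t = xs / chord
        keep = (ys > y_bot(t) + 0.55 * h) & (ys < y_top(t) - 0.55 * h)
        rows.append(np.column_stack([xs[keep], ys[keep]]))
    interior = np.vstack(rows)
    poly = boundary_polygon(spec)
    pts, simplices, edges = _triangulate(boundary, interior, poly)
    return _build_network(
        pts, edges, {"units": "model", "source": f"lens:seed={seed}"}
    )


# ---------------------------------------------------------------------------
# rendering


def render_wing(
    net: PlanarNetwork,
    widths: dict[int, float] | None = None,
    px_per_unit: float = 100.0,
    margin_px: int = 20,
    supersample: int = 4,
) -> np.ndarray:
    """Rasterize a sized network: dark anti-aliased strokes on white.

    Returns a uint8 grayscale array (row 0 at the top of the image; the
    network's y-up frame is flipped on output).  Raises if the thinnest
    member would be under 2 px wide.
    """
    from PIL import Image, ImageDraw

    if widths is None:
        widths = {e.id: e.width for e in net.edges}
    if any(w is None or w <= 0 for w in widths.values()):
        raise GeometryError("all edges need positive widths for rendering")
    if px_per_unit * min(widths.values()) < 2:
        raise GeometryError("resolution below 2 px for the thinnest member")
    pts = np.array(list(net.vertices.values()), dtype=float)
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    size = np.ceil((hi - lo) * px_per_unit).astype(int) + 2 * margin_px
    W, H = int(size[0]), int(size[1])
    S = supersample
    img = Image.new("L", (W * S, H * S), 255)
    draw = ImageDraw.Draw(img)

    def to_px(p):
        q = (np.asarray(p) - lo) * px_per_unit + margin_px
        return (q[0] * S, (H - q[1]) * S)  # flip to raster row order

    for e in net.edges:
        w = max(1, int(round(widths[e.id] * px_per_unit * S)))
        a, b = to_px(net.vertices[e.a]), to_px(net.vertices[e.b])
        draw.line([a, b], fill=0, width=w)
        for p in (a, b):
            r = w / 2
            draw.ellipse([p[0] - r, p[1] - r, p[0] + r, p[1] + r], fill=0)
    img = img.resize((W, H), Image.LANCZOS)
    return np.asarray(img, dtype=np.uint8)


def render_boundary(
    net: PlanarNetwork,
    px_per_unit: float = 100.0,
    stroke_px: float = 3.0,
    margin_px: int = 20,
    canvas: tuple[int, int] | None = None,
) -> np.ndarray:
    """Rasterize only the outline (outer face loop) of a network."""
    from PIL import Image, ImageDraw

    pts = np.array(list(net.vertices.values()), dtype=float)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    if canvas is None:
        size = np.ceil((hi - lo) * px_per_unit).astype(int) + 2 * margin_px
        W, H = int(size[0]), int(size[1])
    else:
        W, H = canvas
        px_per_unit = min(
            (W - 2 * margin_px) / max(hi[0] - lo[0], 1e-9),
            (H - 2 * margin_px) / max(hi[1] - lo[1], 1e-9),
        )
    S = 4
    img = Image.new("L", (W * S, H * S), 255)
    draw = ImageDraw.Draw(img)
    loop = net.outer_face.loop
    path = [
        (
            ((net.vertices[v][0] - lo[0]) * px_per_unit + margin_px) * S,
            (H - ((net.vertices[v][1] - lo[1]) * px_per_unit + margin_px)) * S,
        )
        for v in loop + [loop[0]]
    ]
    draw.line(path, fill=0, width=int(round(stroke_px * S)), joint="curve")
    img = img.resize((W, H), Image.LANCZOS)
    return np.asarray(img, dtype=np.uint8)


# ---------------------------------------------------------------------------
# training corpus


def make_training_corpus(
    n_wings: int = 25,
    spec_ranges: dict | None = None,
    seed: int = 0,
    out_dir=None,
    canvas: tuple[int, int] = (384, 128),
):
    """Synthetic stand-in for a wing photograph collection.

    Per wing: a boundary raster, a main-path encoding of the force
    diagram, and edge-feature records (x1, y1, x2, y2, f) -> form edge
    length.  With 25 wings the split follows the first-21-train /
    last-4-test convention; otherwise the last ~16% are held out.
    """
    from . import codec

    if n_wings < 5:
        raise SpecError("need at least 5 wings for a train/test split")
    ranges = {
        "n_cells": (40, 90),
        "chord": (3.5, 4.5),
        "noise": 0.0,
    }
    ranges.update(spec_ranges or {})
    rng = np.random.default_rng(seed)
    wings = []
    for i in range(n_wings):
        spec = WingSpec(
            n_cells=int(rng.integers(*ranges["n_cells"])),
            chord=float(rng.uniform(*ranges["chord"])),
            noise=float(ranges["noise"]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        net, force, widths = generate_wing(spec)
        boundary_img = render_boundary(net, canvas=canvas)
        mp = codec.encode_wing_main_path(force, canvas=canvas)
        feats = codec.edge_features(net, force)
        wings.append(
            {
                "spec": spec,
                "network": net,
                "force": force,
                "widths": widths,
                "boundary_image": boundary_img,
                "main_path": mp,
                "features": feats,
            }
        )
    n_train = 21 if n_wings == 25 else max(1, int(round(n_wings * 0.84)))
    corpus = {"wings": wings, "train": wings[:n_train], "test": wings[n_train:]}
    if out_dir is not None:
        _write_corpus(corpus, out_dir)
    return corpus


def _write_corpus(corpus, out_dir):
    import csv
    import json
    from pathlib import Path

    from PIL import Image

    from . import codec
    from .network import save_network

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, w in enumerate(corpus["wings"]):
        stem = out / f"wing_{i:03d}"
        save_network(w["network"], f"{stem}.json")
        Image.fromarray(w["boundary_image"]).save(f"{stem}_boundary.png")
        codec.save_main_path(w["main_path"], f"{stem}_mainpath.png")
        rows.extend(w["features"])
    with open(out / "features.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["x1", "y1", "x2", "y2", "f", "target"])
        wr.writerows(rows)
    with open(out / "split.json", "w") as fh:
        json.dump(
            {"n_train": len(corpus["train"]), "n_test": len(corpus["test"])}, fh
        )
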