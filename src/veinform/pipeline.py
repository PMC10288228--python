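"""End-to-end wing regeneration from a boundary outline.

Chains the learned (or fallback) boundary-to-main-path stage, the
main-path decoder, triangulated force-geometry reconstruction, the
edge-length regressor, and the graphic-statics form solve into one
call.  The intermediate force geometry is itself a planar network, so
the resulting form passes the same validation as any other network in
the package.
"""

from __future__ import annotations

import numpy as np

from . import codec
from .models import LengthModel, MainPathTranslator, predict_lengths, translate_boundary_to_mainpath
from .network import Edge, PlanarNetwork
from .reciprocal import (
    DualEdge,
    ForceDiagram,
    _left_right_faces,
    convexify,
    reconstruct_form,
)
from .sizing import size_members


def force_network_as_dual(force_net: PlanarNetwork, _depth: int = 0) -> ForceDiagram:
    """Wrap a force geometry so its reciprocal form can be solved.

    Roles are swapped relative to the usual direction: the faces of the
    force geometry become the unknown form's vertices and every interior
    force edge becomes one form edge (its own dual).  An exact
    perpendicular drawing of the swap is solved first so each form
    edge's tension/compression sense is consistent (obtuse triangle
    pairs flip it); the drawing also seeds the form's placeholder
    coordinates before :func:`veinform.reciprocal.reconstruct_form`
    imposes the predicted lengths.
    """
    from .reciprocal import dual_topology, perpendicularize
    from .synthetic import _circumcenter

    # seed at circumcenters: the Voronoi drawing is the embedded exact
    # reciprocal of a Delaunay-triangulated geometry, and projection
    # leaves it untouched up to float
    dual = dual_topology(force_net)
    for f in force_net.internal_faces:
        # faces are triangles, or cocircular quads from the degeneracy
        # merge below; either way the circumcircle of the first three
        # corners gives the exact dual point
        dual.vertices[f.id] = _circumcenter(
            *[force_net.vertices[v] for v in f.loop[:3]]
        )
    draw, _ = perpendicularize(force_net, dual, method="direct")
    # cocircular triangle pairs give coincident dual vertices (a
    # zero-length form edge); drop the shared force edge so the pair
    # becomes one convex quad, the standard Delaunay degeneracy fix
    lengths = draw.edge_lengths()
    longest = max(lengths.values()) if lengths else 1.0
    tiny = {eid for eid, L in lengths.items() if L < 1e-6 * longest}
    if tiny and _depth < 3:
        from .network import rebuild_faces

        reduced = force_net.copy()
        reduced.edges = [e for e in reduced.edges if e.id not in tiny]
        reduced = rebuild_faces(reduced)
        return force_network_as_dual(reduced, _depth=_depth + 1)
    lr = _left_right_faces(force_net)
    form_vertices = {
        f.id: tuple(map(float, draw.vertices[f.id])) for f in force_net.internal_faces
    }
    form_edges = []
    dual_edges = []
    for e in force_net.edges:
        fl, fr = lr[e.id]
        if fl is None or fr is None or fl.is_outer or fr.is_outer:
            continue
        rho = force_net.edge_vector(e)
        d = np.asarray(form_vertices[fr.id]) - np.asarray(form_vertices[fl.id])
        sign = 1 if float(np.dot(d, np.array([rho[1], -rho[0]]))) >= 0 else -1
        form_edges.append(Edge(e.id, fl.id, fr.id))
        dual_edges.append(DualEdge(id=e.id, form_edge_id=e.id, a=e.a, b=e.b, sign=sign))
    form = PlanarNetwork(
        vertices=form_vertices,
        edges=form_edges,
        faces=[],
        metadata={"units": force_net.metadata.get("units", "px"), "source": "dual of force geometry"},
    )
    return ForceDiagram(
        form=form,
        vertices={v: tuple(force_net.vertices[v]) for v in force_net.vertices},
        edges=dual_edges,
    )


def generate_wing_from_boundary(
    boundary_image: np.ndarray,
    length_model: LengthModel,
    translator: MainPathTranslator | None = None,
    seed: int = 0,
    form_scale: float | None = None,
    d_max: float = 60.0,
    convexify_result: bool = True,
) -> dict:
    """Regenerate a wing network from a boundary raster.

    Returns a dict with the main-path image, the reconstructed force
    geometry, the solved form network, its member sizing, and the
    deviation statistics of the force-to-form solve.
    """
    mp = translate_boundary_to_mainpath(boundary_image, translator, seed=seed)
    decoded = codec.decode_main_path(mp, opening=1 if mp.mode == "model" else 0)
    force_net = codec.reconstruct_force_geometry(decoded)
    fd = force_network_as_dual(force_net)
    if form_scale is None:
        img = np.asarray(boundary_image)
        form_scale = float(np.hypot(*img.shape[:2]))
    targets = predict_lengths(length_model, fd, form_scale)
    # trust region around the seed drawing: the exact (Voronoi-seeded)
    # reciprocal scaled to the predicted global size is planar by
    # construction; predicted lengths then deform it only as far as the
    # embedding survives, with hard perpendicularity throughout
    seed_len = {
        e.id: float(
            np.hypot(*(np.asarray(fd.form.vertices[e.b]) - np.asarray(fd.form.vertices[e.a])))
        )
        for e in fd.form.edges
    }
    ratios = [targets[k] / seed_len[k] for k in targets if seed_len[k] > 1e-9]
    s_star = float(np.median(ratios)) if ratios else 1.0
    ref = {v: (s_star * x, s_star * y) for v, (x, y) in fd.form.vertices.items()}
    vids = sorted(ref)
    far = max(vids, key=lambda v: np.hypot(*(np.asarray(ref[v]) - np.asarray(ref[vids[0]]))))
    anchors = {vids[0]: ref[vids[0]], far: ref[far]}
    form = None
    stats = None
    for lam in (0.0, 0.01, 0.1, 1.0, 10.0, 1e4):
        form, stats = reconstruct_form(
            fd,
            targets,
            anchors,
            direction_weight=300.0,
            proximity=(lam, ref) if lam > 0 else None,
        )
        if form.metadata.get("embedding_valid", False):
            form.metadata["proximity_weight"] = lam
            break
    if convexify_result and form.metadata.get("embedding_valid", False):
        form = convexify(form)
    sizing = size_members(fd, d_max=d_max)
    return {
        "main_path": mp,
        "force_network": force_net,
        "force": fd,
        "form": form,
        "sizing": sizing,
        "deviation": stats,
        "mode": mp.mode,
    }
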