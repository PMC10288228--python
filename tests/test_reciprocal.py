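import math
from fractions import Fraction

import numpy as np
import pytest

from veinform.errors import PreconditionError
from veinform.network import Edge, build_faces, count_vef
from veinform.reciprocal import (
    consistent_anchors,
    convexify,
    dual_topology,
    gdof,
    is_convex_face,
    node_closure_residuals,
    perpendicularize,
    reconstruct_form,
    repair_t_joints,
)

from conftest import make_fan, make_grid, make_triangle, make_two_squares, make_two_triangles


# ---------------------------------------------------------------------------
# independent oracle: exact-rational nullity of the dual closure system


def rational_closure_nullity(net):
    """Gaussian elimination over exact rationals.

    Builds the same per-face closure system as ``gdof`` but with raw
    (unnormalized) edge vectors as exact fractions; column scaling does
    not change the nullity, so the two must agree.
    """
    eids = [e.id for e in net.edges]
    col = {eid: i for i, eid in enumerate(eids)}
    by_pair = {frozenset((e.a, e.b)): e for e in net.edges}
    rows = []
    for f in net.internal_faces:
        loop = f.loop
        rx = [Fraction(0)] * len(eids)
        ry = [Fraction(0)] * len(eids)
        for i in range(len(loop)):
            a, b = loop[i], loop[(i + 1) % len(loop)]
            e = by_pair[frozenset((a, b))]
            ux = Fraction(net.vertices[e.b][0]) - Fraction(net.vertices[e.a][0])
            uy = Fraction(net.vertices[e.b][1]) - Fraction(net.vertices[e.a][1])
            sigma = 1 if (e.a, e.b) == (a, b) else -1
            rx[col[e.id]] += sigma * ux
            ry[col[e.id]] += sigma * uy
        rows.append(rx)
        rows.append(ry)
    # row-reduce
    rank = 0
    ncols = len(eids)
    pivot_col = 0
    rows = [list(r) for r in rows]
    for pivot_col in range(ncols):
        piv = None
        for r in range(rank, len(rows)):
            if rows[r][pivot_col] != 0:
                piv = r
                break
        if piv is None:
            continue
        rows[rank], rows[piv] = rows[piv], rows[rank]
        pr = rows[rank]
        for r in range(len(rows)):
            if r != rank and rows[r][pivot_col] != 0:
                factor = rows[r][pivot_col] / pr[pivot_col]
                rows[r] = [a - factor * b for a, b in zip(rows[r], pr)]
        rank += 1
    return ncols - rank


class TestGdof:
    def test_single_triangle_scale_only(self, triangle):
        assert gdof(triangle) == 1

    def test_fully_triangulated_is_determinate(self, wing50):
        net, _, _ = wing50
        assert gdof(net) == 1

    def test_two_quads_indeterminate(self, two_squares):
        assert gdof(two_squares) >= 2

    @pytest.mark.parametrize(
        "factory",
        [make_triangle, make_two_triangles, make_two_squares,
         lambda: make_fan(3), lambda: make_fan(4, irregular=True),
         lambda: make_grid(1, 1), lambda: make_grid(2, 1)],
    )
    def test_matches_exact_rational_oracle(self, factory):
        net = factory()
        assert len(net.edges) <= 8 or len(net.interior_edges()) <= 8
        assert gdof(net) == rational_closure_nullity(net)

    def test_empty_internal_network_is_domain_error(self):
        net = make_triangle()
        net.faces = [f for f in net.faces if f.is_outer]
        with pytest.raises(PreconditionError):
            gdof(net)


class TestDualTopology:
    def test_two_triangles(self, two_triangles):
        d = dual_topology(two_triangles)
        assert len(d.vertices) == 2
        assert len(d.edges) == 1

    def test_fan_dual_face_size(self):
        net = make_fan(5)
        d = dual_topology(net)
        # the dual face around the hub has one edge per spoke
        assert len(d.vertices) == 5
        assert len(d.edges) == 5

    def test_duality_bijections_on_wing(self, wing50):
        net, _, _ = wing50
        d = dual_topology(net)
        assert len(d.vertices) == len(net.internal_faces)
        assert len(d.edges) == len(net.interior_edges())

    def test_reflex_face_rejected(self):
        vs = {0: (0, 0), 1: (2, 0), 2: (2, 2), 3: (1, 0.5), 4: (0, 2)}
        es = [Edge(0, 0, 1), Edge(1, 1, 2), Edge(2, 2, 3), Edge(3, 3, 4), Edge(4, 4, 0)]
        net = build_faces(vs, es)
        with pytest.raises(PreconditionError):
            dual_topology(net)


class TestPerpendicularize:
    def test_already_reciprocal_pair_converges_immediately(self, wing50):
        net, force, _ = wing50
        stats_deltas = []
        from veinform.reciprocal import _deviations

        per = _deviations(force)
        assert max(per.values()) <= 1e-9

    def test_iterative_reaches_tolerance(self, wing50):
        net, _, _ = wing50
        force, stats = perpendicularize(net, tol_deg=0.01)
        assert stats.converged
        assert stats.mean_delta <= 0.01

    def test_defect_monotone_non_increasing(self, wing50):
        net, _, _ = wing50
        _, stats = perpendicularize(net, tol_deg=1e-4, max_iter=500)
        resid = np.array(stats.residual_history)
        assert np.all(np.diff(resid) <= 1e-12 * resid[0])

    def test_normalized_longest_edge(self, wing50):
        net, _, _ = wing50
        force, _ = perpendicularize(net, tol_deg=0.01, scale=1.0)
        assert max(force.edge_length(de) for de in force.edges) == pytest.approx(1.0)

    def test_scale_covariance(self, two_triangles):
        f1, _ = perpendicularize(two_triangles, method="direct")
        scaled = two_triangles.copy()
        scaled.vertices = {v: (3 * x, 3 * y) for v, (x, y) in scaled.vertices.items()}
        scaled = build_faces(scaled.vertices, scaled.edges)
        f2, _ = perpendicularize(scaled, method="direct")
        l1 = sorted(f1.edge_lengths().values())
        l2 = sorted(f2.edge_lengths().values())
        assert l1 == pytest.approx(l2)  # both normalized to longest = 1

    def test_degenerate_single_face_trivially_converged(self, triangle):
        force, stats = perpendicularize(triangle)
        assert stats.converged
        assert stats.mean_delta == 0.0
        assert len(force.edges) == 0

    def test_node_equilibrium_closure(self, wing50):
        net, force, _ = wing50
        res = node_closure_residuals(net, force)
        fmax = max(force.edge_lengths().values())
        assert res  # the wing has internal vertices
        assert max(res.values()) <= 1e-6 * fmax


class TestReconstructForm:
    def test_round_trip_recovers_geometry(self, wing50):
        net, force, _ = wing50
        targets = {
            de.form_edge_id: net.edge_length(net.edge_by_id(de.form_edge_id))
            for de in force.edges
        }
        vids = sorted(net.vertices)
        anchors = {vids[0]: net.vertices[vids[0]], vids[-1]: net.vertices[vids[-1]]}
        rec, stats = reconstruct_form(force, targets, anchors)
        # similarity alignment: anchors already pin it; compare directly
        err = np.array(
            [np.subtract(rec.vertices[v], net.vertices[v]) for v in vids]
        )
        rms = float(np.sqrt((err**2).sum(axis=1).mean()))
        assert rms <= 1e-6 * net.bbox_diagonal()
        assert stats.mean_delta <= 0.64

    def test_scaling_targets_scales_output(self):
        net = make_fan(5, irregular=True)
        force, _ = perpendicularize(net, method="direct")
        targets = {
            de.form_edge_id: net.edge_length(net.edge_by_id(de.form_edge_id))
            for de in force.edges
        }
        anchors = {0: tuple(net.vertices[0]), 1: tuple(net.vertices[1])}
        r1, _ = reconstruct_form(force, targets, anchors)
        anchors2 = {v: (2 * x, 2 * y) for v, (x, y) in anchors.items()}
        r2, _ = reconstruct_form(
            force, {k: 2 * v for k, v in targets.items()}, anchors2
        )
        for v in r1.vertices:
            assert np.allclose(2 * np.asarray(r1.vertices[v]), r2.vertices[v], atol=1e-9)

    def test_missing_anchors_rejected(self, wing50):
        net, force, _ = wing50
        targets = {de.form_edge_id: 1.0 for de in force.edges}
        with pytest.raises(PreconditionError):
            reconstruct_form(force, targets, {0: (0.0, 0.0)})

    def test_consistent_anchor_helper(self, wing50):
        net, force, _ = wing50
        targets = {
            de.form_edge_id: net.edge_length(net.edge_by_id(de.form_edge_id))
            for de in force.edges
        }
        anchors = consistent_anchors(force, targets)
        assert len(anchors) == 2
        rec, stats = reconstruct_form(force, targets, anchors)
        assert stats.mean_delta <= 0.64


class TestRepairAndConvexify:
    def test_t_joint_offset_breaks_collinearity(self):
        vs = {0: (0, 0), 1: (2, 0), 2: (4, 0), 3: (2, 2), 4: (0, 2), 5: (4, 2)}
        es = [
            Edge(0, 0, 1), Edge(1, 1, 2), Edge(2, 1, 3),  # T at vertex 1
            Edge(3, 0, 4), Edge(4, 4, 3), Edge(5, 3, 5), Edge(6, 5, 2),
        ]
        net = build_faces(vs, es)
        out = repair_t_joints(net, epsilon=0.02)
        assert 1 in out.metadata.get("t_joints_repaired", [])
        p = np.asarray(out.vertices[1])
        d01 = p - np.asarray(out.vertices[0])
        d12 = np.asarray(out.vertices[2]) - p
        cosang = np.dot(d01, d12) / np.linalg.norm(d01) / np.linalg.norm(d12)
        assert cosang < 1.0 - 1e-8  # no longer collinear

    def test_no_t_joints_identity(self, wing50):
        net, _, _ = wing50
        out = repair_t_joints(net)
        for v in net.vertices:
            # Y joints in a triangulation are already non-collinear
            assert out.vertices[v] == pytest.approx(net.vertices[v])

    def test_convexify_fixed_point_on_convex_mesh(self, wing50):
        net, _, _ = wing50
        out = convexify(net)
        assert out.metadata["convexify_displacement"] == 0.0
        assert out.metadata["convexify_converged"]

    def test_convexify_repairs_reflex_quad(self):
        # hexagon split into three quads by a degree-3 hub pulled off
        # center, which makes one quad reflex at the hub
        vs = {i: (math.cos(math.pi * i / 3), math.sin(math.pi * i / 3)) for i in range(6)}
        vs[6] = (0.0, 0.62)
        es = [Edge(i, i, (i + 1) % 6) for i in range(6)] + [
            Edge(6, 0, 6), Edge(7, 2, 6), Edge(8, 4, 6)
        ]
        net = build_faces(vs, es)
        assert not all(is_convex_face(net, f) for f in net.internal_faces)
        out = convexify(net, max_iter=300)
        assert all(is_convex_face(out, f) for f in out.internal_faces)
        disp = out.metadata["convexify_displacement"]
        diam = out.bbox_diagonal()
        assert 0 < disp <= diam
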