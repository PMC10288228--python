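import numpy as np
import pytest

from veinform.errors import AlignmentError, GeometryError, PreconditionError
from veinform.reciprocal import DualEdge, ForceDiagram, perpendicularize
from veinform.sizing import (
    minkowski_unified,
    size_members,
    thickness_accuracy,
    virtual_boundary_forces,
)

from conftest import make_fan


def force_from_lengths(lengths):
    """A synthetic star-shaped force diagram with prescribed edge lengths."""
    verts = {0: (0.0, 0.0)}
    edges = []
    for i, (eid, L) in enumerate(sorted(lengths.items())):
        ang = 0.1 + 2.399 * i  # golden-angle spread, no collinearity
        verts[i + 1] = (L * np.cos(ang), L * np.sin(ang))
        edges.append(DualEdge(id=eid, form_edge_id=eid, a=0, b=i + 1))
    return ForceDiagram(form=None, vertices=verts, edges=edges)


class TestSizeMembers:
    def test_one_to_ten_ratio_maps_to_6_60_px(self):
        force = force_from_lengths({0: 1.0, 1: 10.0, 2: 4.0})
        s = size_members(force, d_max=60.0)
        assert s.diameter[1] == pytest.approx(60.0)
        assert s.diameter[0] == pytest.approx(6.0)

    def test_half_force_half_diameter(self):
        force = force_from_lengths({0: 5.0, 1: 10.0})
        s = size_members(force, d_max=60.0)
        assert s.diameter[0] == pytest.approx(30.0)

    def test_equal_forces_equal_diameters(self):
        force = force_from_lengths({0: 3.0, 1: 3.0, 2: 3.0})
        s = size_members(force, d_max=42.0)
        assert all(d == pytest.approx(42.0) for d in s.diameter.values())

    def test_strict_proportionality_and_normalization(self, wing50):
        _, force, _ = wing50
        s = size_members(force, d_max=60.0)
        F = force.edge_lengths()
        for eid, d in s.diameter.items():
            if eid not in s.zero_force_edges:
                assert d == pytest.approx(s.k * F[eid])
        assert max(s.normalized_radius.values()) == pytest.approx(1.0)

    def test_zero_force_member_floored_and_flagged(self):
        force = force_from_lengths({0: 10.0, 1: 1.0})
        force.vertices[2] = force.vertices[0]  # collapse edge 1
        s = size_members(force, d_max=60.0)
        assert s.zero_force_edges == [1]
        assert s.diameter[1] == pytest.approx(60.0 / 20.0)

    def test_doubling_dmax_doubles_diameters_keeps_theta(self, wing50):
        _, force, widths = wing50
        s1 = size_members(force, d_max=60.0)
        s2 = size_members(force, d_max=120.0)
        for eid in s1.diameter:
            assert s2.diameter[eid] == pytest.approx(2 * s1.diameter[eid])
        w = {k: widths[k] for k in s1.diameter}
        t1 = thickness_accuracy(w, s1)
        t2 = thickness_accuracy(w, s2)
        assert t1.mean_theta == pytest.approx(t2.mean_theta)


class TestThicknessAccuracy:
    def test_identical_radii_give_theta_one(self, wing50):
        _, force, widths = wing50
        s = size_members(force, d_max=60.0)
        acc = thickness_accuracy({k: widths[k] for k in s.diameter}, s)
        assert acc.mean_theta == pytest.approx(1.0)
        assert acc.min_theta == pytest.approx(1.0)

    def test_single_deviation_formula(self):
        force = force_from_lengths({0: 10.0, 1: 9.0})
        s = size_members(force, d_max=10.0)
        acc = thickness_accuracy({0: 10.0, 1: 10.0}, s)
        # R_real = (1.0, 1.0); R_generated = (1.0, 0.9)
        assert acc.per_edge_theta[1] == pytest.approx(0.9)

    def test_planted_five_percent_noise_mean_theta(self, wing50):
        _, force, _ = wing50
        s = size_members(force, d_max=60.0)
        rng = np.random.default_rng(11)
        noisy = {
            eid: d * (1.0 + rng.uniform(-0.05, 0.05))
            for eid, d in s.diameter.items()
        }
        acc = thickness_accuracy(noisy, s)
        assert acc.mean_theta >= 0.95

    def test_mismatched_edge_sets_rejected(self):
        force = force_from_lengths({0: 1.0, 1: 2.0})
        s = size_members(force, d_max=10.0)
        with pytest.raises(AlignmentError):
            thickness_accuracy({0: 1.0}, s)

    def test_weighted_mean_reported_with_lengths(self, wing50):
        net, force, widths = wing50
        s = size_members(force, d_max=60.0)
        lengths = {
            eid: net.edge_length(net.edge_by_id(eid)) for eid in s.diameter
        }
        acc = thickness_accuracy({k: widths[k] for k in s.diameter}, s, lengths)
        assert acc.weighted_mean_theta == pytest.approx(1.0)


class TestVirtualBoundaryForces:
    def test_global_equilibrium(self, wing50):
        net, force, widths = wing50
        s = size_members(force, d_max=60.0)
        bw = {e.id: widths[e.id] for e in net.edges if e.boundary}
        loads, polys = virtual_boundary_forces(net, force, s, bw)
        fmax = max(abs(f) for f in loads.boundary_force.values())
        total = np.sum([loads.loads[v] for v in loads.loads], axis=0)
        assert np.hypot(*total) <= 1e-6 * fmax
        assert loads.residual_norm <= 1e-6 * fmax

    def test_force_polygons_close(self, wing50):
        net, force, widths = wing50
        s = size_members(force, d_max=60.0)
        bw = {e.id: widths[e.id] for e in net.edges if e.boundary}
        _, polys = virtual_boundary_forces(net, force, s, bw)
        for v, chain in polys.items():
            assert np.allclose(chain[-1], (0.0, 0.0), atol=1e-9)

    def test_node_by_node_oracle(self, wing50):
        """Independent per-node vector arithmetic must give the same loads."""
        net, force, widths = wing50
        s = size_members(force, d_max=60.0)
        bw = {e.id: widths[e.id] for e in net.edges if e.boundary}
        loads, _ = virtual_boundary_forces(net, force, s, bw)
        from veinform.sizing import member_axial_forces

        axial = member_axial_forces(force)
        inc = net.vertex_edges()
        for v in net.outer_face.loop:
            expect = np.zeros(2)
            for e in inc[v]:
                phi = axial[e.id] if e.id in axial else bw[e.id] / s.k
                w = e.b if e.a == v else e.a
                d = net.coords(w) - net.coords(v)
                expect -= phi * d / np.hypot(*d)
            assert np.allclose(loads.loads[v], expect, atol=1e-9)

    def test_symmetric_wing_symmetric_loads(self):
        net = make_fan(6)  # regular fan is mirror symmetric about the x axis
        force, _ = perpendicularize(net, method="direct")
        s = size_members(force, d_max=10.0)
        bw = {e.id: 5.0 for e in net.edges if e.boundary}
        loads, _ = virtual_boundary_forces(net, force, s, bw)
        # mirror pairs: rim vertex at angle a <-> at angle -a
        pts = {v: np.asarray(net.vertices[v]) for v in loads.loads}
        for v, p in pts.items():
            mirror = min(
                pts, key=lambda u: np.linalg.norm(pts[u] - np.array([p[0], -p[1]]))
            )
            lv, lm = np.asarray(loads.loads[v]), np.asarray(loads.loads[mirror])
            assert np.allclose(lv, [lm[0], -lm[1]], atol=1e-8)

    def test_missing_boundary_width_rejected(self, wing50):
        net, force, widths = wing50
        s = size_members(force, d_max=60.0)
        bw = {e.id: widths[e.id] for e in net.edges if e.boundary}
        bw.pop(next(iter(bw)))
        with pytest.raises(PreconditionError):
            virtual_boundary_forces(net, force, s, bw)


class TestMinkowskiUnified:
    def test_zero_scale_limit_is_bare_form(self):
        net = make_fan(6)
        force, _ = perpendicularize(net, method="direct")
        uni = minkowski_unified(net, force, scale=0.0, validate=False)
        for f in net.internal_faces:
            assert uni.cells[f.id].area == pytest.approx(net.face_polygon(f).area)
        for eid, quad in uni.members.items():
            assert quad.area == pytest.approx(0.0, abs=1e-12)

    def test_member_widths_proportional_to_forces(self):
        net = make_fan(5, irregular=True)
        force, _ = perpendicularize(net, method="direct")
        scale = 0.1
        uni = minkowski_unified(net, force, scale=scale)
        F = force.edge_lengths()
        for de in force.edges:
            fe = net.edge_by_id(de.form_edge_id)
            quad = uni.members[de.form_edge_id]
            expected = net.edge_length(fe) * scale * F[de.form_edge_id]
            assert quad.area == pytest.approx(expected, rel=1e-9)

    def test_polygons_tile_without_overlap(self):
        net = make_fan(6, irregular=True)
        force, _ = perpendicularize(net, method="direct")
        uni = minkowski_unified(net, force, scale=0.15)
        assert uni.total_area() == pytest.approx(uni.union_area(), rel=1e-6)

    def test_inverting_scale_rejected(self):
        # the opposite combination sign folds member quads onto the
        # cells, which the tiling validation must reject
        net = make_fan(6, irregular=True)
        force, _ = perpendicularize(net, method="direct")
        with pytest.raises(GeometryError):
            minkowski_unified(net, force, scale=-0.15)
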