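import math

import numpy as np
import pytest
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from veinform import codec
from veinform.errors import CodecError, ReconstructionError, VectorizationError
from veinform.network import count_vef
from veinform.reciprocal import DualEdge, ForceDiagram, dual_topology
from veinform.synthetic import WingSpec, generate_wing, lens_mesh, render_wing


def star_force(lengths, center=(0.0, 0.0)):
    verts = {0: center}
    edges = []
    for i, (eid, L) in enumerate(sorted(lengths.items())):
        ang = 0.2 + 2.399 * i
        verts[i + 1] = (center[0] + L * math.cos(ang), center[1] + L * math.sin(ang))
        edges.append(DualEdge(id=eid, form_edge_id=eid, a=0, b=i + 1))
    return ForceDiagram(form=None, vertices=verts, edges=edges)


class TestEncode:
    def test_max_length_quantizes_to_255(self):
        force = star_force({0: 10.0})
        region = Polygon([(-12, -12), (12, -12), (12, 12), (-12, 12)])
        mp = codec.encode_main_path(force, [region], 64, 64, L_min=1.0, L_max=10.0)
        b = np.argwhere(mp.pixels[..., 2] == 255)
        assert len(b) == 1
        assert mp.pixels[b[0][0], b[0][1], 1] == 255

    def test_mid_length_rounds_to_128(self):
        # L = (L_min + L_max)/2 -> G = round(127.5) = 128
        force = star_force({0: 5.5})
        region = Polygon([(-7, -7), (7, -7), (7, 7), (-7, 7)])
        mp = codec.encode_main_path(force, [region], 64, 64, L_min=1.0, L_max=10.0)
        b = np.argwhere(mp.pixels[..., 2] == 255)
        assert mp.pixels[b[0][0], b[0][1], 1] == 128

    def test_g_positive_only_at_midpoints(self, wing50):
        _, force, _ = wing50
        mp = codec.encode_wing_main_path(force)
        g_on = mp.pixels[..., 1] > 0
        b_on = mp.pixels[..., 2] == 255
        assert np.all(~g_on | b_on)

    def test_colliding_midpoints_rejected(self):
        force = star_force({0: 5.0, 1: 5.02})
        region = Polygon([(-7, -7), (7, -7), (7, 7), (-7, 7)])
        with pytest.raises(CodecError):
            codec.encode_main_path(force, [region], 16, 16, L_min=1.0, L_max=10.0)


class TestDecodeRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_midpoints_and_lengths_recovered(self, seed):
        _, force, _ = generate_wing(WingSpec(n_cells=50, seed=seed))
        mp = codec.encode_wing_main_path(force)
        dec = codec.decode_main_path(mp)
        F = force.edge_lengths()
        eids = sorted(F, key=F.get, reverse=True)
        top = eids[: max(1, math.ceil(len(eids) / 10))]
        by_id = {de.form_edge_id: de for de in force.edges}
        truths = [
            (
                mp.world_to_px((force.coords(by_id[e].a) + force.coords(by_id[e].b)) / 2),
                F[e],
            )
            for e in top
        ]
        assert len(dec.midpoints_px) == len(top)
        tree = cKDTree([t[0] for t in truths])
        step = (mp.l_max - mp.l_min) / 255
        for rc, L in zip(dec.midpoints_px, dec.lengths):
            d, j = tree.query(rc)
            assert d <= 1.0
            assert abs(L - truths[j][1]) <= step + 1e-12

    def test_two_regions_decoded_separately(self):
        f1 = star_force({0: 4.0, 1: 5.0, 2: 6.0}, center=(0.0, 0.0))
        f2 = star_force({3: 4.0, 4: 5.0}, center=(40.0, 0.0))
        combined = ForceDiagram(
            form=None,
            vertices={**f1.vertices, **{k + 10: v for k, v in f2.vertices.items()}},
            edges=f1.edges
            + [DualEdge(d.id, d.form_edge_id, d.a + 10, d.b + 10) for d in f2.edges],
        )
        regions = [
            Polygon([(-8, -8), (8, -8), (8, 8), (-8, 8)]),
            Polygon([(32, -8), (48, -8), (48, 8), (32, 8)]),
        ]
        mp = codec.encode_main_path(combined, regions, 96, 256, L_min=1.0, L_max=8.0)
        dec = codec.decode_main_path(mp)
        assert len(dec.region_masks) == 2
        assert len(dec.midpoints_px) == 5

    def test_isolated_midpoint_pixels_discarded(self, wing50):
        _, force, _ = wing50
        mp = codec.encode_wing_main_path(force)
        px = mp.pixels.copy()
        px[2, 2, 2] = 255  # B pixel far from any region
        corrupted = codec.MainPathImage(
            px, mp.l_min, mp.l_max, mp.px_per_unit, mp.origin
        )
        with pytest.warns(UserWarning, match="discarded"):
            dec = codec.decode_main_path(corrupted)
        clean = codec.decode_main_path(mp)
        assert len(dec.midpoints_px) == len(clean.midpoints_px)

    def test_robust_to_salt_and_pepper_with_opening(self, wing50):
        _, force, _ = wing50
        mp = codec.encode_wing_main_path(force)
        rng = np.random.default_rng(0)
        px = mp.pixels.copy()
        flip = rng.random(px.shape[:2]) < 0.01
        px[..., 0] = np.where(flip, 255 - px[..., 0], px[..., 0])
        noisy = codec.MainPathImage(px, mp.l_min, mp.l_max, mp.px_per_unit, mp.origin)
        dec = codec.decode_main_path(noisy, opening=1)
        clean = codec.decode_main_path(mp)
        assert len(dec.region_masks) == len(clean.region_masks)

    def test_no_region_is_error(self):
        blank = codec.MainPathImage(
            np.zeros((32, 32, 3), np.uint8), 1.0, 2.0, 1.0, (0.0, 0.0)
        )
        with pytest.raises(CodecError):
            codec.decode_main_path(blank)


class TestReconstructForceGeometry:
    def _strip_fixture(self, n_sites=6, seed=0):
        """A region polygon with interior sites and the expected
        triangulation built directly (the independent oracle)."""
        rng = np.random.default_rng(seed)
        region = Polygon([(10, 10), (190, 10), (190, 80), (10, 80)])
        sites = []
        for i in range(n_sites):
            x = 35 + i * 130 / max(n_sites - 1, 1) + rng.uniform(-4, 4)
            y = 40 + rng.uniform(-8, 8)
            sites.append((x, y))
        return region, sites

    def test_round_trip_against_direct_construction(self):
        region, sites = self._strip_fixture()
        corners = np.asarray(region.exterior.coords)[:-1]
        # encode: region + one synthetic midpoint pixel per site
        mp = codec.encode_main_path(
            ForceDiagram(form=None, vertices={0: (0, 0), 1: (200, 90)}, edges=[]),
            [region],
            128,
            256,
            L_min=1.0,
            L_max=10.0,
        )
        for x, y in sites:
            r, c = np.round(mp.world_to_px((x, y))).astype(int)
            mp.pixels[r, c, 2] = 255
            mp.pixels[r, c, 1] = 100
        dec = codec.decode_main_path(mp)
        net = codec.reconstruct_force_geometry(dec, simplify_tol=1.5)
        # every encoded corner and site recovered within 2 px
        rec = np.array(list(net.vertices.values()))
        tol = 2.0 / mp.px_per_unit
        d, _ = cKDTree(rec).query(np.vstack([corners, sites]))
        assert d.max() <= tol
        # face count obeys the exact combinatorial identity for a
        # triangulated disc: F = 2*I + B - 2 (independent Euler oracle)
        B = len(net.outer_face.loop)
        I = len(net.vertices) - B
        assert len(net.internal_faces) == 2 * I + B - 2
        assert all(len(f.loop) == 3 for f in net.internal_faces)
        # reconstructed geometry must satisfy the dual preconditions
        dual_topology(net)

    def test_triangles_only(self):
        region, sites = self._strip_fixture(n_sites=3, seed=1)
        mp = codec.encode_main_path(
            ForceDiagram(form=None, vertices={0: (0, 0), 1: (200, 90)}, edges=[]),
            [region], 128, 256, L_min=1.0, L_max=10.0,
        )
        for x, y in sites:
            r, c = np.round(mp.world_to_px((x, y))).astype(int)
            mp.pixels[r, c, 2] = 255
            mp.pixels[r, c, 1] = 100
        net = codec.reconstruct_force_geometry(codec.decode_main_path(mp))
        assert all(len(f.loop) == 3 for f in net.internal_faces)

    def test_collinear_region_is_error(self):
        # a region whose boundary collapses to a straight segment cannot
        # be triangulated
        dec = codec.DecodedMainPath(
            region_masks=[np.ones((8, 64), bool)],
            region_polygons_px=[
                np.array([[4.0, c] for c in np.linspace(2, 60, 30)])
            ],
            skeletons=[np.zeros((8, 64), bool)],
            midpoints_px=[],
            lengths=[],
            boundary_polylines_px=[],
        )
        with pytest.raises(ReconstructionError):
            codec.reconstruct_force_geometry(dec)

    def test_no_region_is_error(self):
        dec = codec.DecodedMainPath([], [], [], [], [], [])
        with pytest.raises(ReconstructionError):
            codec.reconstruct_force_geometry(dec)


class TestVectorize:
    def test_blank_image_is_error(self):
        with pytest.raises(VectorizationError):
            codec.vectorize_wing_image(np.full((64, 64), 255, np.uint8))

    def test_triangle_recovered_with_widths(self, triangle):
        scaled = triangle.copy()
        scaled.vertices = {v: (200 * x + 20, 200 * y + 20) for v, (x, y) in scaled.vertices.items()}
        from veinform.network import build_faces

        scaled = build_faces(scaled.vertices, scaled.edges)
        img = render_wing(scaled, widths={e.id: 5.0 for e in scaled.edges}, px_per_unit=1.0, margin_px=10)
        net = codec.vectorize_wing_image(img)
        assert count_vef(net) == (3, 3, 1)
        for e in net.edges:
            assert e.width == pytest.approx(5.0, abs=1.5)

    def test_grid_of_cells_recovered(self):
        from conftest import make_grid

        grid = make_grid(2, 2, spacing=80.0)
        img = render_wing(grid, widths={e.id: 6.0 for e in grid.edges}, px_per_unit=1.0, margin_px=12)
        net = codec.vectorize_wing_image(img)
        assert count_vef(net) == count_vef(grid)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_lens_mesh_round_trip_3_to_15_px(self, seed):
        net = lens_mesh(n_rows=4, seed=seed)
        rng = np.random.default_rng(100 + seed)
        ppu = 300.0
        widths = {e.id: float(rng.uniform(3, 15)) for e in net.edges}
        img = render_wing(
            net, widths={k: v / ppu for k, v in widths.items()}, px_per_unit=ppu, margin_px=30
        )
        rec = codec.vectorize_wing_image(img)
        assert count_vef(rec) == count_vef(net)
        # width recovery: >= 95% of edges within 1 px
        tv = np.array([net.coords(v) for v in sorted(net.vertices)]) * ppu
        tv -= tv.min(axis=0)
        rids = sorted(rec.vertices)
        rvv = np.array([rec.coords(v) for v in rids])
        rvv -= rvv.min(axis=0)
        _, idx = cKDTree(rvv).query(tv)
        vmap = {sv: rids[i] for sv, i in zip(sorted(net.vertices), idx)}
        by_pair = {frozenset((e.a, e.b)): e for e in rec.edges}
        errs = []
        for e in net.edges:
            re = by_pair[frozenset((vmap[e.a], vmap[e.b]))]
            errs.append(abs(re.width - widths[e.id]))
        assert np.mean(np.asarray(errs) <= 1.0) >= 0.95

    def test_wing_render_recovers_faces(self):
        net, _, widths = generate_wing(WingSpec(n_cells=30, seed=0))
        ppu = 300.0
        w = {e.id: float(np.clip(widths[e.id] / 60 * 8, 3, 8)) / ppu for e in net.edges}
        img = render_wing(net, widths=w, px_per_unit=ppu, margin_px=25)
        rec = codec.vectorize_wing_image(img)
        assert len(rec.internal_faces) == len(net.internal_faces)

    def test_doubling_resolution_doubles_widths(self):
        net = lens_mesh(n_rows=4, seed=3)
        base = {e.id: 6.0 / 300.0 for e in net.edges}
        img1 = render_wing(net, widths=base, px_per_unit=300.0, margin_px=25)
        img2 = render_wing(net, widths=base, px_per_unit=600.0, margin_px=25)
        r1 = codec.vectorize_wing_image(img1)
        r2 = codec.vectorize_wing_image(img2)
        m1 = np.median([e.width for e in r1.edges])
        m2 = np.median([e.width for e in r2.edges])
        assert m2 == pytest.approx(2 * m1, abs=1.2)
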