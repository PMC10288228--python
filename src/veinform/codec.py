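"""Raster codecs: wing vectorization and the force main-path image.

The *main path* of a force diagram (the region holding the large
triangles of the primary veins) is serialized as an RGB raster:

* ``R`` in {0, 255}: membership of a main-path region;
* ``B`` in {0, 255}: a force-edge midpoint lies in this pixel;
* ``G``: the force-edge length, linearly quantized between the
  ``L_min``/``L_max`` recorded in the sidecar metadata, valid only
  where ``B`` is set;
* all-zero pixels adjacent to a region are the region's boundary
  curve (the "black channel").

The codec is tolerant on decode (channels thresholded at 128, optional
morphological opening) so rasters emitted by a learned translator can
be consumed by the same reader.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import unary_union
from skimage.measure import approximate_polygon, find_contours, label
from skimage.morphology import skeletonize

from .errors import CodecError, ReconstructionError, VectorizationError
from .network import Edge, PlanarNetwork, build_faces
from .reciprocal import ForceDiagram


@dataclass
class MainPathImage:
    """RGB raster of a force main path plus its quantization sidecar."""

    pixels: np.ndarray  # (H, W, 3) uint8
    l_min: float
    l_max: float
    px_per_unit: float
    origin: tuple[float, float]  # world coords of pixel (row=H-1-margin ...)
    mode: str = "encoded"  # encoded | fallback | model

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def quantize(self, length: float) -> int:
        rng = self.l_max - self.l_min
        g = round(255.0 * (length - self.l_min) / rng) if rng > 0 else 0
        return int(np.clip(g, 0, 255))

    def dequantize(self, g: int) -> float:
        return self.l_min + (self.l_max - self.l_min) * float(g) / 255.0

    def world_to_px(self, xy) -> tuple[float, float]:
        x, y = xy
        H = self.pixels.shape[0]
        col = (x - self.origin[0]) * self.px_per_unit
        row = (H - 1) - (y - self.origin[1]) * self.px_per_unit
        return (row, col)

    def px_to_world(self, rowcol) -> tuple[float, float]:
        row, col = rowcol
        H = self.pixels.shape[0]
        x = self.origin[0] + col / self.px_per_unit
        y = self.origin[1] + ((H - 1) - row) / self.px_per_unit
        return (x, y)


@dataclass
class DecodedMainPath:
    """Decoder output: regions, midpoints with lengths, boundaries."""

    region_masks: list[np.ndarray]
    region_polygons_px: list[np.ndarray]  # (N, 2) row/col polylines
    skeletons: list[np.ndarray]
    midpoints_px: list[tuple[float, float]]  # (row, col)
    lengths: list[float]
    boundary_polylines_px: list[np.ndarray]
    meta: MainPathImage | None = None


# ---------------------------------------------------------------------------
# encoding


def encode_main_path(
    force: ForceDiagram,
    main_path_region_polygons: list[Polygon],
    H: int,
    W: int,
    L_min: float,
    L_max: float,
    margin: int = 8,
    mode: str = "encoded",
    edge_ids: list[int] | None = None,
) -> MainPathImage:
    """Rasterize a force diagram's main path into channel semantics.

    Force edges whose midpoint falls inside a region polygon contribute
    one midpoint pixel (``B=255``) carrying their quantized length in
    ``G``.  Region interiors are filled in ``R`` and outlined with a
    one-pixel all-zero boundary curve.  Two midpoints landing on the
    same pixel raise :class:`CodecError` (increase the resolution).
    """
    from PIL import Image, ImageDraw

    if not (L_max > L_min > 0):
        raise CodecError("need L_max > L_min > 0 for length quantization")
    pts = np.array(
        [force.coords(v) for v in force.vertices]
        + [np.asarray(p) for poly in main_path_region_polygons for p in poly.exterior.coords],
        dtype=float,
    )
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    ppu = min(
        (W - 2 * margin) / max(hi[0] - lo[0], 1e-9),
        (H - 2 * margin) / max(hi[1] - lo[1], 1e-9),
    )
    origin = (float(lo[0] - margin / ppu), float(lo[1] - margin / ppu))
    mp = MainPathImage(
        pixels=np.zeros((H, W, 3), dtype=np.uint8),
        l_min=float(L_min),
        l_max=float(L_max),
        px_per_unit=float(ppu),
        origin=origin,
        mode=mode,
    )

    img = Image.new("L", (W, H), 0)
    draw = ImageDraw.Draw(img)
    outline = Image.new("L", (W, H), 0)
    odraw = ImageDraw.Draw(outline)
    for poly in main_path_region_polygons:
        ring = [mp.world_to_px(p)[::-1] for p in poly.exterior.coords]
        draw.polygon(ring, fill=255)
        odraw.line(ring + [ring[0]], fill=255, width=1)
    rmask = np.asarray(img) >= 128
    omask = np.asarray(outline) >= 128
    mp.pixels[..., 0] = np.where(rmask & ~omask, 255, 0)

    used = {}
    for de in force.edges:
        a, b = force.coords(de.a), force.coords(de.b)
        mid = (a + b) / 2.0
        if edge_ids is not None:
            if de.form_edge_id not in edge_ids:
                continue
        elif not any(poly.covers(Point(mid)) for poly in main_path_region_polygons):
            continue
        row, col = np.round(mp.world_to_px(mid)).astype(int)
        if not (0 <= row < H and 0 <= col < W):
            raise CodecError(f"midpoint of edge {de.id} falls outside the canvas")
        for key in used:
            if max(abs(key[0] - row), abs(key[1] - col)) <= 1:
                raise CodecError(
                    f"midpoints of edges {used[key]} and {de.id} collide at "
                    f"pixels {key}/{(row, col)}; use a higher resolution"
                )
        used[(row, col)] = de.id
        length = float(np.hypot(*(b - a)))
        mp.pixels[row, col, 2] = 255
        mp.pixels[row, col, 1] = mp.quantize(length)
        mp.pixels[row, col, 0] = mp.pixels[row, col, 0]  # keep region bit
    return mp


def save_main_path(mp: MainPathImage, path) -> None:
    from PIL import Image

    Image.fromarray(mp.pixels, mode="RGB").save(path)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "L_min": mp.l_min,
                "L_max": mp.l_max,
                "px_per_unit": mp.px_per_unit,
                "origin": list(mp.origin),
                "mode": mp.mode,
            },
            fh,
        )


def load_main_path(path) -> MainPathImage:
    from PIL import Image

    pixels = np.asarray(Image.open(path).convert("RGB"))
    with open(str(path) + ".json") as fh:
        side = json.load(fh)
    return MainPathImage(
        pixels=pixels,
        l_min=side["L_min"],
        l_max=side["L_max"],
        px_per_unit=side["px_per_unit"],
        origin=tuple(side["origin"]),
        mode=side.get("mode", "encoded"),
    )


# ---------------------------------------------------------------------------
# decoding


def decode_main_path(image: MainPathImage, opening: int = 0) -> DecodedMainPath:
    """Recover regions, midpoints and boundary curves from a raster.

    ``R`` and ``B`` are thresholded at 128 so slightly off outputs of a
    learned generator still decode; ``opening`` applies a morphological
    opening of that radius to the region mask first (use 1 for ragged
    model output).  Midpoint pixels outside any region are discarded
    with a warning.
    """
    px = image.pixels
    rmask = px[..., 0] >= 128
    if opening > 0:
        rmask = ndimage.binary_opening(rmask, structure=np.ones((2 * opening + 1,) * 2))
        rmask = ndimage.binary_closing(rmask, structure=np.ones((2 * opening + 1,) * 2))
    if not rmask.any():
        raise CodecError("no main-path region found in the R channel")
    labels, n_regions = label(rmask, connectivity=2, return_num=True)
    masks = [labels == i for i in range(1, n_regions + 1)]
    # drop specks (below 0.1% of the canvas)
    min_px = max(9, int(0.001 * rmask.size))
    masks = [m for m in masks if m.sum() >= min_px] or masks

    region_polys = []
    skeletons = []
    near_region = ndimage.binary_dilation(
        np.logical_or.reduce([m for m in masks]), iterations=2
    )
    for m in masks:
        # the one-pixel black rim delimits the region but belongs to its
        # footprint; dilating before contouring restores the true outline
        filled = ndimage.binary_fill_holes(
            ndimage.binary_dilation(m, structure=np.ones((3, 3), bool))
        )
        cont = find_contours(filled.astype(float), 0.5)
        cont = max(cont, key=len) if cont else np.empty((0, 2))
        region_polys.append(cont)
        skeletons.append(skeletonize(filled))

    bmask = px[..., 2] >= 128
    in_any = np.logical_or.reduce([ndimage.binary_dilation(m, iterations=1) for m in masks])
    blab, nb = label(bmask, connectivity=2, return_num=True)
    midpoints, lengths = [], []
    dropped = 0
    for i in range(1, nb + 1):
        ys, xs = np.nonzero(blab == i)
        if not in_any[ys, xs].any():
            dropped += 1
            continue
        g = float(px[ys, xs, 1].max())
        midpoints.append((float(ys.mean()), float(xs.mean())))
        lengths.append(image.dequantize(g))
    if dropped:
        warnings.warn(f"discarded {dropped} midpoint clusters outside any region")

    # boundary: all-zero pixels adjacent to a region
    zero = np.all(px < 128, axis=-1)
    bnd = zero & near_region
    boundary_polylines = [c for c in find_contours(bnd.astype(float), 0.5)] if bnd.any() else []

    return DecodedMainPath(
        region_masks=masks,
        region_polygons_px=region_polys,
        skeletons=skeletons,
        midpoints_px=midpoints,
        lengths=lengths,
        boundary_polylines_px=boundary_polylines,
        meta=image,
    )


# ---------------------------------------------------------------------------
# force-geometry reconstruction


def _skeleton_junctions(skel: np.ndarray) -> list[tuple[float, float]]:
    """Centroids of skeleton pixels with three or more neighbours."""
    nb = ndimage.convolve(skel.astype(int), np.ones((3, 3), int), mode="constant")
    junc = skel & (nb >= 4)  # self + >= 3 neighbours
    if not junc.any():
        return []
    lab, n = label(junc, connectivity=2, return_num=True)
    out = []
    for i in range(1, n + 1):
        ys, xs = np.nonzero(lab == i)
        out.append((float(ys.mean()), float(xs.mean())))
    return out


def reconstruct_force_geometry(
    decoded: DecodedMainPath,
    simplify_tol: float = 1.5,
    region_index: int | None = None,
) -> PlanarNetwork:
    """Rebuild a convex (triangulated) force geometry from a main path.

    The external polygon comes from the region boundary simplified at
    ``simplify_tol`` px; internal vertices are skeleton junction
    points; the interior is Delaunay-triangulated, so every face is
    convex by construction.  Coordinates are in force-diagram units
    when the decoder carried metadata, else pixels (y-up).
    """
    if not decoded.region_masks:
        raise ReconstructionError("decoded main path has no regions")
    if region_index is None:
        region_index = int(np.argmax([m.sum() for m in decoded.region_masks]))
    poly_px = decoded.region_polygons_px[region_index]
    if len(poly_px) < 4:
        raise ReconstructionError("region boundary too short to form a polygon")
    simplified = approximate_polygon(poly_px, tolerance=simplify_tol)
    if len(simplified) > 1 and np.allclose(simplified[0], simplified[-1]):
        simplified = simplified[:-1]
    if len(simplified) < 3:
        raise ReconstructionError("region boundary degenerates under simplification")

    # internal sites: skeleton junctions plus decoded midpoints (the
    # midpoints of a triangulation-dominant main path sample the band
    # interior at cell density, so they recover the triangulation sites)
    shp = Polygon([(c, r) for r, c in simplified])
    if not shp.is_valid:
        shp = shp.buffer(0)
    mask = decoded.region_masks[region_index]
    mids = [
        (r, c)
        for r, c in decoded.midpoints_px
        if mask[int(round(r)) % mask.shape[0], int(round(c)) % mask.shape[1]]
    ]
    # midpoints are the designed interior sites; skeleton junctions only
    # stand in when a raster carries no usable midpoint data (the band
    # skeleton is ragged enough to produce spurious junctions otherwise)
    candidates = mids if len(mids) >= 3 else _skeleton_junctions(
        decoded.skeletons[region_index]
    ) + mids
    if len(candidates) >= 2:
        arr = np.asarray(candidates, dtype=float)
        d2 = np.sum((arr[:, None, :] - arr[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        spacing = float(np.median(np.sqrt(d2.min(axis=1))))
    else:
        spacing = math.sqrt(max(shp.area, 1.0))
    # sites too close to the outline or to each other would triangulate
    # into slivers whose reciprocal is wildly distorted
    margin = max(2.0 * simplify_tol, 0.55 * spacing)
    inner = shp.buffer(-margin)
    internal = [(r, c) for r, c in candidates if inner.covers(Point(c, r))]
    kept: list[tuple[float, float]] = []
    for r, c in internal:
        if all(
            np.hypot(r - r2, c - c2) > max(2.0 * simplify_tol, 0.6 * spacing)
            for r2, c2 in kept
        ):
            kept.append((r, c))

    # densify the outline so boundary segments match the interior site
    # spacing
    ring = []
    n_b = len(simplified)
    centroid = np.asarray(simplified, dtype=float).mean(axis=0)
    for i in range(n_b):
        p, q = np.asarray(simplified[i]), np.asarray(simplified[(i + 1) % n_b])
        ring.append(tuple(p))
        seg = float(np.hypot(*(q - p)))
        n_sub = int(seg // (1.3 * spacing))
        if seg > 0:
            normal = np.array([-(q - p)[1], (q - p)[0]]) / seg
            if float(np.dot(normal, centroid - (p + q) / 2)) < 0:
                normal = -normal
        for k in range(1, n_sub + 1):
            s = p + (q - p) * k / (n_sub + 1)
            # small inward offset along the segment normal: exactly
            # collinear points degenerate the triangulation
            ring.append(tuple(s + 0.5 * normal))

    pts_px = np.array(ring + kept, dtype=float)

    def to_world(rc):
        if decoded.meta is not None:
            return decoded.meta.px_to_world(rc)
        return (float(rc[1]), -float(rc[0]))

    pts = np.array([to_world(p) for p in pts_px])
    try:
        tri = Delaunay(pts)
    except Exception as exc:
        raise ReconstructionError(f"triangulation failed: {exc}") from exc
    cent_px = pts_px[tri.simplices].mean(axis=1)
    inside = np.array([shp.covers(Point(c, r)) for r, c in cent_px])
    simplices = tri.simplices[inside]
    if not len(simplices):
        raise ReconstructionError("no triangle lies inside the region")
    edges = set()
    for s in simplices:
        for i in range(3):
            edges.add(frozenset((int(s[i]), int(s[(i + 1) % 3]))))
    vertices = {i: (float(p[0]), float(p[1])) for i, p in enumerate(pts)}
    used = sorted({v for e in edges for v in e})
    vertices = {v: vertices[v] for v in used}
    edge_objs = [Edge(i, *sorted(e)) for i, e in enumerate(sorted(edges, key=sorted))]
    net = build_faces(
        vertices,
        edge_objs,
        metadata={
            "units": "force" if decoded.meta is not None else "px",
            "source": "main-path reconstruction",
            "n_regions": len(decoded.region_masks),
        },
    )
    if len(net.internal_faces) != len(simplices):
        raise ReconstructionError(
            "triangulation produced open or non-convex polygons"
        )
    # attach decoded lengths to the nearest reconstructed edge midpoint
    if decoded.midpoints_px:
        mids_world = np.array([to_world(p) for p in decoded.midpoints_px])
        emids = {
            e.id: (np.asarray(net.vertices[e.a]) + np.asarray(net.vertices[e.b])) / 2
            for e in net.edges
        }
        eids = list(emids)
        tree = cKDTree(np.array([emids[i] for i in eids]))
        enc = {}
        for m, L in zip(mids_world, decoded.lengths):
            _, j = tree.query(m)
            enc[eids[int(j)]] = L
        net.metadata["encoded_lengths"] = enc
    return net


# ---------------------------------------------------------------------------
# wing image vectorization


def vectorize_wing_image(
    image: np.ndarray,
    threshold: float | None = None,
    invert: bool = False,
    min_spur_px: float | None = None,
    merge_radius: float | None = None,
) -> PlanarNetwork:
    """Trace a wing raster into a network with per-edge widths.

    Pipeline: binarize (Otsu unless ``threshold`` given) -> skeletonize
    -> junction/endpoint detection -> path tracing -> straight edges
    between junction clusters; width is twice the median distance
    transform along the traced centerline (robust to junction blobs).
    Raster rows are flipped so the output is y-up, in pixels.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    img = img.astype(float)
    if threshold is None:
        from skimage.filters import threshold_otsu

        if img.min() == img.max():
            raise VectorizationError("blank image: nothing to vectorize")
        threshold = float(threshold_otsu(img))
    mask = img > threshold if invert else img < threshold
    if not mask.any():
        raise VectorizationError("empty mask after thresholding")
    skel = skeletonize(mask)
    edt = ndimage.distance_transform_edt(mask)

    H, W = mask.shape
    sk_idx = {tuple(p): i for i, p in enumerate(np.argwhere(skel))}
    if not sk_idx:
        raise VectorizationError("skeleton is empty")

    def neighbours(p):
        r, c = p
        out = []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                q = (r + dr, c + dc)
                if q in sk_idx:
                    out.append(q)
        return out

    deg = {p: len(neighbours(p)) for p in sk_idx}
    junction_px = [p for p, d in deg.items() if d >= 3]
    endpoints = [p for p, d in deg.items() if d == 1]

    if merge_radius is None:
        merge_radius = max(2.0, 1.3 * float(np.median([edt[p] for p in junction_px])) if junction_px else 2.0)
    # cluster junction pixels within the merge radius
    node_of: dict[tuple[int, int], int] = {}
    clusters: list[list[tuple[int, int]]] = []
    if junction_px:
        pts = np.array(junction_px, dtype=float)
        tree = cKDTree(pts)
        pairs = tree.query_pairs(merge_radius)
        parent = list(range(len(junction_px)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in pairs:
            parent[find(i)] = find(j)
        roots = {}
        for i, p in enumerate(junction_px):
            r = find(i)
            roots.setdefault(r, []).append(p)
        for pxs in roots.values():
            node_of.update({p: len(clusters) for p in pxs})
            clusters.append(pxs)
    for p in endpoints:
        node_of[p] = len(clusters)
        clusters.append([p])

    # trace paths between nodes, plus node-free cycles (closed outlines)
    visited = set()
    raw_paths = []  # (node_a | None, node_b | None, pixel path)
    for start in sorted(node_of):
        for nb0 in neighbours(start):
            if nb0 in node_of and node_of[nb0] == node_of[start]:
                continue
            if (start, nb0) in visited:
                continue
            path = [start, nb0]
            visited.add((start, nb0))
            prev, cur = start, nb0
            while cur not in node_of:
                visited.add((prev, cur))
                nxt = [q for q in neighbours(cur) if q != prev]
                if not nxt:
                    break
                prev, cur = cur, nxt[0]
                path.append(cur)
            if cur in node_of:
                visited.add((prev, cur))
                visited.add((cur, prev))
                raw_paths.append((node_of[start], node_of[cur], path))
    traced = {p for *_ab, path in raw_paths for p in path}
    for start in sorted(sk_idx):
        if start in traced or start in node_of or deg[start] != 2:
            continue
        path = [start]
        prev, cur = None, start
        while True:
            nxt = [q for q in neighbours(cur) if q != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            if cur == start:
                break
            path.append(cur)
        if cur == start and len(path) >= 8:
            traced |= set(path)
            raw_paths.append((None, None, path + [start]))

    centroids = [np.mean(np.array(c, dtype=float), axis=0) for c in clusters]
    if min_spur_px is None:
        min_spur_px = 3.0
    corner_tol = 2.2

    def seg_width(pixels):
        vals = [edt[p] for p in pixels]
        k = len(vals)
        if k > 6:
            vals = vals[k // 4 : k - k // 4]
        return 2.0 * float(np.median(vals))

    # collect straight segments, splitting paths at geometric corners
    points: list[tuple[float, float]] = [tuple(c) for c in centroids]
    segments = []  # (point_index_a, point_index_b, pixel chain)
    endpoint_nodes = {node_of[p] for p in endpoints}

    def add_point(rc) -> int:
        points.append((float(rc[0]), float(rc[1])))
        return len(points) - 1

    for a, b, path in raw_paths:
        arr = np.array(path, dtype=float)
        closed = a is None
        simp = approximate_polygon(arr, tolerance=corner_tol)
        # indices of breakpoints within the pixel chain
        breaks = [0]
        j = 0
        for sp in simp[1:-1]:
            j = int(np.argmin(np.sum((arr[j:] - sp) ** 2, axis=1))) + j
            breaks.append(j)
        breaks.append(len(arr) - 1)
        node_ids = []
        for k, bidx in enumerate(breaks):
            if not closed and k == 0:
                node_ids.append(a)
            elif not closed and k == len(breaks) - 1:
                node_ids.append(b)
            elif closed and k == len(breaks) - 1:
                node_ids.append(node_ids[0])
            else:
                node_ids.append(add_point(arr[bidx]))
        for k in range(len(breaks) - 1):
            chain = path[breaks[k] : breaks[k + 1] + 1]
            na, nb = node_ids[k], node_ids[k + 1]
            if na == nb and len(chain) < 8:
                continue
            w = seg_width(chain)
            spur = (
                not closed
                and ((k == 0 and a in endpoint_nodes) or (k == len(breaks) - 2 and b in endpoint_nodes))
            )
            if spur and len(chain) < max(min_spur_px, 1.5 * w):
                continue
            segments.append((na, nb, w, len(chain), chain))

    if not segments:
        raise VectorizationError("no edges traced between junctions")
    edge_map = {}
    for na, nb, w, ln, chain in segments:
        if na == nb:
            continue
        key = (min(na, nb), max(na, nb))
        if key not in edge_map or ln > edge_map[key][1]:
            edge_map[key] = (w, ln, set(chain))
    adj: dict[int, dict[int, tuple]] = {}
    for (a, b), (w, ln, pix) in sorted(edge_map.items()):
        adj.setdefault(a, {})[b] = (w, ln, pix)
        adj.setdefault(b, {})[a] = (w, ln, pix)

    def _dist(a, b):
        return float(np.hypot(points[a][0] - points[b][0], points[a][1] - points[b][1]))

    def contract_short(strong_limit=2.0):
        """Collapse skeleton fragments shorter than the local stroke width
        (junction blobs of wide strokes shatter into such pieces)."""
        changed = False
        for a in sorted(adj):
            if a not in adj:
                continue
            for b in list(adj.get(a, {})):
                if b not in adj or a not in adj:
                    break
                w_node = max(
                    max(rec[0] for rec in adj[a].values()),
                    max(rec[0] for rec in adj[b].values()),
                    4.0,
                )
                if len(adj[a]) >= 3 and len(adj[b]) >= 3:
                    limit = max(6.0, strong_limit * max(adj[a][b][0], 4.0))
                else:
                    limit = max(6.0, 1.2 * w_node)
                if _dist(a, b) >= limit:
                    continue
                pa, pb = np.array(points[a]), np.array(points[b])
                points[a] = tuple((pa + pb) / 2)
                for c, rec in list(adj[b].items()):
                    if c == a:
                        continue
                    del adj[c][b]
                    if c in adj[a]:
                        old = adj[a][c]
                        keep = rec if rec[1] > old[1] else old
                        merged = (keep[0], keep[1], old[2] | rec[2])
                        adj[a][c] = merged
                        adj[c][a] = merged
                    else:
                        adj[a][c] = rec
                        adj[c][a] = rec
                del adj[a][b]
                del adj[b]
                changed = True
        return changed

    def straighten():
        """Contract degree-2 points whose edges are nearly collinear
        (corner splitting is deliberately eager; this undoes false
        corners)."""
        changed = False
        for v in list(adj):
            if len(adj.get(v, {})) != 2:
                continue
            (na, (wa, la, pixa)), (nb, (wb, lb, pixb)) = adj[v].items()
            if na == nb:
                continue
            pa = np.array(points[na]) - np.array(points[v])
            pb = np.array(points[nb]) - np.array(points[v])
            cosang = float(np.dot(pa, pb) / (np.linalg.norm(pa) * np.linalg.norm(pb)))
            # lateral deviation of v from the chord na-nb
            chord = np.array(points[nb]) - np.array(points[na])
            perp = abs(float(chord[0] * (-pa[1]) - chord[1] * (-pa[0]))) / max(
                np.linalg.norm(chord), 1e-9
            )
            w_local = max(wa, wb)
            if cosang > -math.cos(math.radians(14.0)) and perp > max(2.5, 0.55 * w_local):
                continue  # a genuine corner
            if nb in adj.get(na, {}):
                continue  # would create a duplicate edge
            w = (wa * la + wb * lb) / (la + lb)
            rec = (w, la + lb, pixa | pixb)
            del adj[na][v]
            del adj[nb][v]
            del adj[v]
            adj[na][nb] = rec
            adj[nb][na] = rec
            changed = True
        return changed

    def repair_crossings():
        """Contract the shorter edge of any crossing pair (crossings come
        from blob-displaced nodes, always at junction scale)."""
        segs, keys = [], []
        for a in sorted(adj):
            for b in adj[a]:
                if a < b:
                    segs.append(LineString([points[a], points[b]]))
                    keys.append((a, b))
        from shapely.strtree import STRtree

        tree = STRtree(segs)
        for i, s in enumerate(segs):
            a, b = keys[i]
            if a not in adj or b not in adj.get(a, {}):
                continue
            for j in tree.query(s):
                j = int(j)
                if j <= i:
                    continue
                c, d_ = keys[j]
                if {a, b} & {c, d_}:
                    continue
                if c not in adj or d_ not in adj.get(c, {}):
                    continue
                if not s.intersects(segs[j]):
                    continue
                # contract the shorter of the two edges
                (u, v) = (a, b) if _dist(a, b) <= _dist(c, d_) else (c, d_)
                pa, pb = np.array(points[u]), np.array(points[v])
                points[u] = tuple((pa + pb) / 2)
                for w_, rec in list(adj[v].items()):
                    if w_ == u:
                        continue
                    del adj[w_][v]
                    if w_ not in adj[u]:
                        adj[u][w_] = rec
                        adj[w_][u] = rec
                del adj[u][v]
                del adj[v]
                return True
        return False

    def refit_positions():
        """Re-estimate every vertex as the least-squares intersection of
        the lines fitted to its incident edges' reliable mid-pixels
        (junction blobs displace skeleton-based centroids)."""
        lines = {}
        for a in sorted(adj):
            for b in adj[a]:
                if a > b:
                    continue
                w, ln, pix = adj[a][b]
                arr = np.array(sorted(pix), dtype=float)
                pa, pb = np.array(points[a]), np.array(points[b])
                r_cut = 1.4 * max(w, 3.0) + 2.0
                da = np.linalg.norm(arr - pa, axis=1)
                db = np.linalg.norm(arr - pb, axis=1)
                good = arr[(da > r_cut) & (db > r_cut)]
                if len(good) < 5:
                    good = arr
                mu = good.mean(axis=0)
                cen = good - mu
                _, _, vt = np.linalg.svd(cen, full_matrices=False)
                lines[(a, b)] = (mu, vt[0])
        for v in sorted(adj):
            incident = [lines[(min(v, u), max(v, u))] for u in adj[v]]
            if len(incident) < 2:
                continue
            A = np.zeros((2, 2))
            rhs = np.zeros(2)
            for mu, d in incident:
                n = np.array([-d[1], d[0]])
                A += np.outer(n, n)
                rhs += n * float(np.dot(n, mu))
            if np.linalg.cond(A) > 1e4:
                continue
            sol = np.linalg.solve(A, rhs)
            w_local = max(max(rec[0] for rec in adj[v].values()), 3.0)
            if np.linalg.norm(sol - np.array(points[v])) <= 1.6 * w_local:
                points[v] = (float(sol[0]), float(sol[1]))

    for _ in range(8):
        c1 = contract_short(strong_limit=1.0)
        c2 = straighten()
        if not (c1 or c2):
            break
    refit_positions()
    for _ in range(8):
        c1 = contract_short(strong_limit=1.2)
        c2 = straighten()
        if not (c1 or c2):
            break
    refit_positions()
    for _ in range(12):
        if not repair_crossings():
            break
        straighten()

    used_nodes = sorted(adj)
    remap = {n: i for i, n in enumerate(used_nodes)}
    vertices = {
        remap[n]: (float(points[n][1]), float(H - 1 - points[n][0])) for n in used_nodes
    }
    seen = set()
    edges = []
    for a in used_nodes:
        for b, (w, ln, pix) in adj[a].items():
            key = (min(a, b), max(a, b))
            if key in seen:
                continue
            seen.add(key)
            edges.append(Edge(len(edges), remap[key[0]], remap[key[1]], width=w))
    try:
        net = build_faces(
            vertices, edges, metadata={"units": "px", "source": "vectorized"}
        )
    except Exception as exc:
        raise VectorizationError(f"traced network is not a planar embedding: {exc}") from exc
    return net


# ---------------------------------------------------------------------------
# main-path helpers used by the synthetic corpus


def main_path_region(
    force: ForceDiagram, top_fraction: float = 0.1, buffer_factor: float = 0.45
) -> Polygon:
    """Region polygon covering the top-force dual edges (the main path)."""
    F = force.edge_lengths()
    eids = sorted(F, key=F.get, reverse=True)
    n_top = max(1, int(math.ceil(len(eids) * top_fraction)))
    top = eids[:n_top]
    by_id = {de.form_edge_id: de for de in force.edges}
    segs = []
    for eid in top:
        de = by_id[eid]
        segs.append(LineString([force.coords(de.a), force.coords(de.b)]))
    med = float(np.median([s.length for s in segs]))
    poly = unary_union([s.buffer(buffer_factor * med) for s in segs])
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    return poly.simplify(0.1 * med)


def encode_wing_main_path(
    force: ForceDiagram, canvas: tuple[int, int] = (384, 128), top_fraction: float = 0.1
) -> MainPathImage:
    """Encode the top-force band of a wing's force diagram."""
    region = main_path_region(force, top_fraction)
    F = force.edge_lengths()
    eids = sorted(F, key=F.get, reverse=True)
    n_top = max(1, int(math.ceil(len(eids) * top_fraction)))
    top = eids[:n_top]
    lengths = [F[eid] for eid in top]
    L_min, L_max = min(lengths), max(lengths)
    if L_max <= L_min:
        L_max = L_min * 1.01 + 1e-9
    W, H = canvas
    last = None
    for _ in range(4):  # grow the canvas until no midpoints collide
        try:
            return encode_main_path(force, [region], H, W, L_min, L_max, edge_ids=top)
        except CodecError as exc:
            if "collide" not in str(exc):
                raise
            last = exc
            W, H = int(W * 1.5), int(H * 1.5)
    raise last


def edge_features(
    net: PlanarNetwork, force: ForceDiagram
) -> list[tuple[float, float, float, float, float, float]]:
    """(x1, y1, x2, y2, f) -> form edge length records for the regressor.

    Dual endpoint coordinates are normalized to the force diagram's
    bounding box, f to the maximum force; the target form length is
    normalized by the form's bounding-box diagonal.
    """
    pts = np.array([force.coords(v) for v in force.vertices])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.maximum(hi - lo, 1e-12)
    F = force.edge_lengths()
    f_max = max(F.values())
    form_scale = net.bbox_diagonal()
    rows = []
    for de in force.edges:
        a = (force.coords(de.a) - lo) / span
        b = (force.coords(de.b) - lo) / span
        fe = net.edge_by_id(de.form_edge_id)
        rows.append(
            (
                float(a[0]),
                float(a[1]),
                float(b[0]),
                float(b[1]),
                float(F[de.form_edge_id] / f_max),
                float(net.edge_length(fe) / form_scale),
            )
        )
    return rows
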