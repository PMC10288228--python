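"""Morphometric comparison of networks and geometry export.

Real and regenerated wings are compared cell by cell on area and
circularity (the ratio of a cell's area to the area of the circle with
its perimeter), the measures summarized with an energy-distance
statistic on the joint (area, circularity) cloud.  Networks and unified
diagrams export to SVG (width-proportional strokes, re-importable) and
to watertight extruded STL for printing.
"""

from __future__ import annotations

import json

import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ExportError, PreconditionError
from .network import Edge, PlanarNetwork, build_faces, count_vef, face_metrics
from .sizing import UnifiedDiagram


def energy_distance_2d(x: np.ndarray, y: np.ndarray) -> float:
    """Székely's energy distance between two 2-D point clouds."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exy = cdist(x, y).mean()
    exx = cdist(x, x).mean()
    eyy = cdist(y, y).mean()
    return float(max(2.0 * exy - exx - eyy, 0.0))


def _summary(values: np.ndarray) -> dict:
    q = np.quantile(values, [0.1, 0.25, 0.5, 0.75, 0.9])
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "q10": float(q[0]),
        "q25": float(q[1]),
        "median": float(q[2]),
        "q75": float(q[3]),
        "q90": float(q[4]),
    }


@dataclass
class ComparisonReport:
    """Self-contained morphometric comparison of two networks."""

    counts_real: tuple[int, int, int]
    counts_generated: tuple[int, int, int]
    cells_real: list[dict]
    cells_generated: list[dict]
    summaries: dict
    energy_distance: float
    count_mismatch: bool
    thickness: dict | None = None
    deviation: dict | None = None

    def to_json_dict(self) -> dict:
        return asdict(self)


def compare_networks(
    real: PlanarNetwork,
    generated: PlanarNetwork,
    plot_path=None,
    thickness: dict | None = None,
    deviation: dict | None = None,
) -> ComparisonReport:
    """Compare two wing networks on per-cell area and circularity.

    Areas are normalized by each network's total cell area so networks
    digitized at different scales remain comparable; the energy
    distance is computed on the joint (normalized area, circularity)
    cloud.  Optionally writes a scatter + smoothed-curve + count-bar
    figure to ``plot_path``.
    """
    for name, net in (("real", real), ("generated", generated)):
        if not net.internal_faces:
            raise PreconditionError(f"{name} network has no internal faces")
    mr = face_metrics(real)
    mg = face_metrics(generated)
    ar = np.array([m.area for m in mr])
    ag = np.array([m.area for m in mg])
    cr = np.array([m.circularity for m in mr])
    cg = np.array([m.circularity for m in mg])
    arn, agn = ar / ar.sum(), ag / ag.sum()
    cloud_r = np.column_stack([arn, cr])
    cloud_g = np.column_stack([agn, cg])
    report = ComparisonReport(
        counts_real=count_vef(real),
        counts_generated=count_vef(generated),
        cells_real=[asdict(m) for m in mr],
        cells_generated=[asdict(m) for m in mg],
        summaries={
            "area_real": _summary(ar),
            "area_generated": _summary(ag),
            "circularity_real": _summary(cr),
            "circularity_generated": _summary(cg),
        },
        energy_distance=energy_distance_2d(cloud_r, cloud_g),
        count_mismatch=count_vef(real) != count_vef(generated),
        thickness=thickness,
        deviation=deviation,
    )
    if plot_path is not None:
        _comparison_figure(report, arn, cr, agn, cg, plot_path)
    return report


def _comparison_figure(report, arn, cr, agn, cg, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    axes[0].scatter(arn, cr, s=12, c="tab:orange", label="real", alpha=0.7)
    axes[0].scatter(agn, cg, s=12, c="tab:green", label="generated", alpha=0.7)
    axes[0].set_xlabel("normalized cell area")
    axes[0].set_ylabel("circularity")
    axes[0].legend()
    # kernel-smoothed circularity vs area (Silverman bandwidth)
    for a, c, col in ((arn, cr, "tab:orange"), (agn, cg, "tab:green")):
        order = np.argsort(a)
        a, c = a[order], c[order]
        bw = 1.06 * a.std(ddof=1) * len(a) ** (-1 / 5) if len(a) > 1 else 0.1
        bw = max(bw, 1e-6)
        grid = np.linspace(a.min(), a.max(), 100)
        w = np.exp(-0.5 * ((grid[:, None] - a[None, :]) / bw) ** 2)
        axes[1].plot(grid, (w * c).sum(axis=1) / w.sum(axis=1), color=col)
    axes[1].set_xlabel("normalized cell area")
    axes[1].set_ylabel("smoothed circularity")
    labels = ["v", "e", "f"]
    xpos = np.arange(3)
    axes[2].bar(xpos - 0.2, report.counts_real, width=0.4, color="tab:orange", label="real")
    axes[2].bar(xpos + 0.2, report.counts_generated, width=0.4, color="tab:green", label="generated")
    axes[2].set_xticks(xpos, labels)
    axes[2].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def save_report(report: ComparisonReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# SVG


def export_svg(
    obj: PlanarNetwork | UnifiedDiagram,
    path,
    stroke_scale: float = 1.0,
    default_width: float = 1.0,
) -> None:
    """Write a network (width-proportional strokes) or unified diagram
    (filled polygons) as SVG.  Network SVGs round-trip through
    :func:`import_svg`."""
    if isinstance(obj, PlanarNetwork):
        pts = np.array(list(obj.vertices.values()), dtype=float)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        pad = 0.05 * max(hi - lo)
        lo, hi = lo - pad, hi + pad
        h = hi[1] - lo[1]
        lines = []
        for e in obj.edges:
            (x1, y1), (x2, y2) = obj.vertices[e.a], obj.vertices[e.b]
            w = (e.width if e.width else default_width) * stroke_scale
            lines.append(
                f'<line x1="{x1 - lo[0]:.4f}" y1="{h - (y1 - lo[1]):.4f}" '
                f'x2="{x2 - lo[0]:.4f}" y2="{h - (y2 - lo[1]):.4f}" '
                f'stroke="black" stroke-width="{w:.4f}" stroke-linecap="round"/>'
            )
        body = "\n".join(lines)
        svg = (
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'width="{hi[0] - lo[0]:.4f}" height="{h:.4f}" '
            f'viewBox="0 0 {hi[0] - lo[0]:.4f} {h:.4f}">\n{body}\n</svg>\n'
        )
    elif isinstance(obj, UnifiedDiagram):
        polys = obj.all_polygons()
        allpts = np.vstack([np.asarray(p.exterior.coords) for p in polys])
        lo = allpts.min(axis=0)
        hi = allpts.max(axis=0)
        h = hi[1] - lo[1]
        parts = []
        for group, colour in (
            (obj.members, "#444444"),
            (obj.nodes, "#888888"),
            (obj.cells, "#dddddd"),
        ):
            for poly in group.values():
                pts_str = " ".join(
                    f"{x - lo[0]:.4f},{h - (y - lo[1]):.4f}"
                    for x, y in poly.exterior.coords
                )
                parts.append(f'<polygon points="{pts_str}" fill="{colour}"/>')
        body = "\n".join(parts)
        svg = (
            f'<svg xmlns="http://www.w3.org/2000/svg" '
            f'width="{hi[0] - lo[0]:.4f}" height="{h:.4f}" '
            f'viewBox="0 0 {hi[0] - lo[0]:.4f} {h:.4f}">\n{body}\n</svg>\n'
        )
    else:
        raise ExportError(f"cannot export object of type {type(obj)}")
    with open(path, "w") as fh:
        fh.write(svg)


def import_svg(path) -> PlanarNetwork:
    """Re-import a network SVG written by :func:`export_svg`."""
    tree = ET.parse(path)
    root = tree.getroot()
    height = float(root.attrib["height"])
    ns = "{http://www.w3.org/2000/svg}"
    vertices: dict[int, tuple[float, float]] = {}
    index: dict[tuple[float, float], int] = {}

    def vid(x, y):
        key = (round(x, 4), round(y, 4))
        if key not in index:
            index[key] = len(index)
            vertices[index[key]] = key
        return index[key]

    edges = []
    for ln in root.iter(f"{ns}line"):
        x1, y1 = float(ln.attrib["x1"]), height - float(ln.attrib["y1"])
        x2, y2 = float(ln.attrib["x2"]), height - float(ln.attrib["y2"])
        w = float(ln.attrib.get("stroke-width", 1.0))
        edges.append(Edge(len(edges), vid(x1, y1), vid(x2, y2), width=w))
    if not edges:
        raise ExportError("no line elements found in SVG")
    return build_faces(vertices, edges, metadata={"units": "px", "source": str(path)})


# ---------------------------------------------------------------------------
# STL


def export_stl(
    obj: UnifiedDiagram | PlanarNetwork,
    path,
    height: float,
    stroke_scale: float = 1.0,
) -> None:
    """Extrude unified-diagram polygons (or stroked members) to STL.

    Each convex polygon becomes a watertight prism: fan-triangulated
    caps with consistent outward normals plus side quads.  Raises
    :class:`ExportError` for non-positive heights or degenerate
    polygons.
    """
    import trimesh

    if height <= 0:
        raise ExportError("extrusion height must be positive")
    if isinstance(obj, UnifiedDiagram):
        polys = [np.asarray(p.exterior.coords)[:-1] for p in obj.all_polygons()]
    else:
        polys = []
        for e in obj.edges:
            a = np.asarray(obj.vertices[e.a])
            b = np.asarray(obj.vertices[e.b])
            w = (e.width or 1.0) * stroke_scale / 2.0
            d = b - a
            n = np.array([-d[1], d[0]]) / max(np.hypot(*d), 1e-12) * w
            polys.append(np.array([a + n, b + n, b - n, a - n]))
    bad = [i for i, p in enumerate(polys) if len(p) < 3]
    if bad:
        raise ExportError(f"degenerate polygons at indices {bad}")

    vertices = []
    faces = []
    for p in polys:
        # enforce CCW so outward normals are consistent
        area = 0.5 * float(
            np.sum(p[:, 0] * np.roll(p[:, 1], -1) - np.roll(p[:, 0], -1) * p[:, 1])
        )
        if area < 0:
            p = p[::-1]
        k = len(p)
        base = len(vertices)
        vertices.extend([(x, y, 0.0) for x, y in p])
        vertices.extend([(x, y, height) for x, y in p])
        for i in range(1, k - 1):  # bottom cap, normal -z
            faces.append((base, base + i + 1, base + i))
        for i in range(1, k - 1):  # top cap, normal +z
            faces.append((base + k, base + k + i, base + k + i + 1))
        for i in range(k):  # sides
            j = (i + 1) % k
            faces.append((base + i, base + j, base + k + j))
            faces.append((base + i, base + k + j, base + k + i))
    mesh = trimesh.Trimesh(
        vertices=np.asarray(vertices, dtype=float),
        faces=np.asarray(faces, dtype=int),
        process=False,
    )
    if not all(m.is_watertight for m in mesh.split(only_watertight=False)):
        raise ExportError("extrusion produced a non-watertight body")
    mesh.export(path, file_type="stl_ascii")
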