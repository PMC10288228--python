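"""Serialization of force diagrams with their correspondence maps."""

from __future__ import annotations

import json

from .network import from_json_dict, to_json_dict
from .reciprocal import DualEdge, ForceDiagram


def force_diagram_to_json_dict(force: ForceDiagram) -> dict:
    return {
        "form": to_json_dict(force.form),
        "scale": force.scale,
        "vertices": [
            {"id": v, "x": x, "y": y} for v, (x, y) in sorted(force.vertices.items())
        ],
        "edges": [
            {
                "id": de.id,
                "form_edge_id": de.form_edge_id,
                "v": [de.a, de.b],
                "sign": de.sign,
            }
            for de in force.edges
        ],
    }


def force_diagram_from_json_dict(data: dict) -> ForceDiagram:
    return ForceDiagram(
        form=from_json_dict(data["form"]),
        vertices={
            int(v["id"]): (float(v["x"]), float(v["y"])) for v in data["vertices"]
        },
        edges=[
            DualEdge(
                id=int(e["id"]),
                form_edge_id=int(e["form_edge_id"]),
                a=int(e["v"][0]),
                b=int(e["v"][1]),
                sign=int(e.get("sign", 1)),
            )
            for e in data["edges"]
        ],
        scale=float(data.get("scale", 1.0)),
    )


def save_force_diagram(force: ForceDiagram, path) -> None:
    with open(path, "w") as fh:
        json.dump(force_diagram_to_json_dict(force), fh, indent=1, sort_keys=True)


def load_force_diagram(path) -> ForceDiagram:
    with open(path) as fh:
        return force_diagram_from_json_dict(json.load(fh))
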