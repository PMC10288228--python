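import math

import numpy as np
import pytest

from veinform.network import Edge, build_faces
from veinform.synthetic import WingSpec, generate_wing


def make_triangle():
    return build_faces(
        {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (0.0, 1.0)},
        [Edge(0, 0, 1), Edge(1, 1, 2), Edge(2, 2, 0)],
    )


def make_square():
    return build_faces(
        {0: (0.0, 0.0), 1: (1.0, 0.0), 2: (1.0, 1.0), 3: (0.0, 1.0)},
        [Edge(0, 0, 1), Edge(1, 1, 2), Edge(2, 2, 3), Edge(3, 3, 0)],
    )


def make_two_squares():
    vs = {0: (0, 0), 1: (1, 0), 2: (2, 0), 3: (2, 1), 4: (1, 1), 5: (0, 1)}
    es = [
        Edge(0, 0, 1), Edge(1, 1, 2), Edge(2, 2, 3), Edge(3, 3, 4),
        Edge(4, 4, 5), Edge(5, 5, 0), Edge(6, 1, 4),
    ]
    return build_faces(vs, es)


def make_two_triangles():
    vs = {0: (0, 0), 1: (1, 0), 2: (1, 1), 3: (0, 1)}
    es = [Edge(0, 0, 1), Edge(1, 1, 2), Edge(2, 2, 3), Edge(3, 3, 0), Edge(4, 0, 2)]
    return build_faces(vs, es)


def make_fan(k=6, irregular=False):
    """k triangles around one interior vertex."""
    vs = {0: (0.0, 0.0)}
    rng = np.random.default_rng(7)
    for i in range(k):
        a = 2 * math.pi * i / k
        r = 1.0 + (0.2 * rng.random() if irregular else 0.0)
        vs[i + 1] = (r * math.cos(a), r * math.sin(a))
    es = [Edge(i, 0, i + 1) for i in range(k)]
    es += [Edge(k + i, i + 1, (i + 1) % k + 1) for i in range(k)]
    return build_faces(vs, es)


def make_grid(nx=2, ny=2, spacing=1.0):
    vs = {}
    for j in range(ny + 1):
        for i in range(nx + 1):
            vs[j * (nx + 1) + i] = (i * spacing, j * spacing)
    es = []
    eid = 0
    for j in range(ny + 1):
        for i in range(nx):
            es.append(Edge(eid, j * (nx + 1) + i, j * (nx + 1) + i + 1))
            eid += 1
    for j in range(ny):
        for i in range(nx + 1):
            es.append(Edge(eid, j * (nx + 1) + i, (j + 1) * (nx + 1) + i))
            eid += 1
    return build_faces(vs, es)


@pytest.fixture(scope="session")
def triangle():
    return make_triangle()


@pytest.fixture(scope="session")
def square():
    return make_square()


@pytest.fixture(scope="session")
def two_squares():
    return make_two_squares()


@pytest.fixture(scope="session")
def two_triangles():
    return make_two_triangles()


@pytest.fixture(scope="session")
def wing50():
    """One 50-cell synthetic wing with its exact reciprocal and widths."""
    return generate_wing(WingSpec(n_cells=50, seed=0))


@pytest.fixture(scope="session")
def wing200():
    """The large synthetic wing used for convergence checks."""
    return generate_wing(WingSpec(n_cells=220, seed=1))


@pytest.fixture(scope="session")
def corpus10():
    from veinform.synthetic import make_training_corpus

    return make_training_corpus(n_wings=10, seed=5)
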