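import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wirebundle.mesh import build_edge_graph, generate_fixture_mesh

FIXTURES = [
    ("triangle", {}),
    ("tetrahedron", {}),
    ("octahedron", {}),
    ("icosahedron", {}),
    ("fan_polygon", {"n": 5}),
    ("fan_polygon", {"n": 6}),
    ("square_rod", {"segments": 3}),
]


def fixture_id(spec):
    name, kw = spec
    suffix = "".join(f"_{v}" for v in kw.values())
    return f"{name}{suffix}"


@pytest.fixture(params=FIXTURES, ids=[fixture_id(f) for f in FIXTURES])
def fixture_mesh(request):
    name, kw = request.param
    return generate_fixture_mesh(name, **kw)


@pytest.fixture
def pentagon_mesh():
    """2D pentagon scaled so that the rim edges come out at 100 bp
    (34 nm) under a unit nm-per-mesh-unit scale."""
    rim = 2 * np.sin(np.pi / 5)
    return generate_fixture_mesh("fan_polygon", n=5, scale=34.0 / rim)


@pytest.fixture
def octahedron_graph():
    return build_edge_graph(generate_fixture_mesh("octahedron"))
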