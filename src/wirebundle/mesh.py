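"""Polygonal meshes, PLY I/O and the edge graph with its rotation system.

A wireframe target shape is a set of vertices and faces.  The scaffold
router does not work on the mesh directly but on its edge multigraph
together with a *rotation system*: the cyclic order of incident edges
around every vertex induced by the surface embedding.  That ordering is
what the A-trail neighbour constraint refers to.

The PLY reader is deliberately small: ASCII and binary-little-endian
files with ``vertex`` (x/y/z) and ``face`` (vertex_indices) elements are
supported and any extra per-vertex properties (normals, colours) are
skipped.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MeshFormatError, MeshValidationError, OrientationError

__all__ = [
    "Mesh",
    "EdgeGraph",
    "read_ply",
    "write_ply",
    "build_edge_graph",
    "generate_fixture_mesh",
    "FIXTURE_NAMES",
]

_PLY_TYPES = {
    "char": ("b", 1), "int8": ("b", 1),
    "uchar": ("B", 1), "uint8": ("B", 1),
    "short": ("h", 2), "int16": ("h", 2),
    "ushort": ("H", 2), "uint16": ("H", 2),
    "int": ("i", 4), "int32": ("i", 4),
    "uint": ("I", 4), "uint32": ("I", 4),
    "float": ("f", 4), "float32": ("f", 4),
    "double": ("d", 8), "float64": ("d", 8),
}


@dataclass(frozen=True)
class Mesh:
    """A polygonal mesh: vertex coordinates plus vertex-index cycles.

    Faces are stored counter-clockwise as given; ``validate`` checks the
    structural invariants (index ranges, >= 3 distinct corners, manifold
    edges), not the geometry.
    """

    vertices: np.ndarray  # (V, 3) float
    faces: tuple[tuple[int, ...], ...]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edge_set(self) -> list[tuple[int, int]]:
        """Distinct undirected edges in deterministic (first-seen) order."""
        seen: dict[tuple[int, int], None] = {}
        for f in self.faces:
            for i, a in enumerate(f):
                b = f[(i + 1) % len(f)]
                seen.setdefault((min(a, b), max(a, b)))
        return list(seen)

    def validate(self) -> None:
        v = self.n_vertices
        if v < 3 or not self.faces:
            raise MeshValidationError("mesh needs >= 3 vertices and >= 1 face")
        edge_faces: dict[tuple[int, int], int] = {}
        for fi, f in enumerate(self.faces):
            if len(f) < 3 or len(set(f)) != len(f):
                raise MeshValidationError(
                    f"face {fi} must have >= 3 distinct vertex indices: {f}")
            for idx in f:
                if not (0 <= idx < v):
                    raise MeshValidationError(
                        f"face {fi} references vertex index {idx} of {v}")
            for i, a in enumerate(f):
                b = f[(i + 1) % len(f)]
                key = (min(a, b), max(a, b))
                edge_faces[key] = edge_faces.get(key, 0) + 1
        bad = [e for e, n in edge_faces.items() if n > 2]
        if bad:
            raise MeshValidationError(
                f"non-manifold edges shared by >2 faces: {bad}")


def read_ply(path: str | Path) -> Mesh:
    """Read a PLY mesh (ASCII or binary little endian) and validate it."""
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header")
    if not raw.startswith(b"ply") or end < 0:
        raise MeshFormatError(f"{path}: not a PLY file (missing header)")
    end = raw.index(b"\n", end) + 1
    header = raw[:end].decode("ascii", errors="replace")
    body = raw[end:]

    fmt = None
    elements: list[tuple[str, int, list[tuple]]] = []  # (name, count, props)
    for line in header.splitlines():
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise MeshFormatError(f"{path}: property before element")
            if tok[1] == "list":
                elements[-1][2].append(("list", tok[2], tok[3], tok[4]))
            else:
                elements[-1][2].append(("scalar", tok[1], tok[2]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshFormatError(f"{path}: unsupported format '{fmt}'")

    data: dict[str, list[dict]] = {}
    if fmt == "ascii":
        rows = body.decode("ascii").split()
        pos = 0

        def take() -> str:
            nonlocal pos
            pos += 1
            return rows[pos - 1]

        try:
            for name, count, props in elements:
                recs = []
                for _ in range(count):
                    rec = {}
                    for p in props:
                        if p[0] == "list":
                            n = int(take())
                            rec[p[3]] = [int(float(take())) for _ in range(n)]
                        else:
                            rec[p[2]] = float(take())
                    recs.append(rec)
                data[name] = recs
        except (IndexError, ValueError) as exc:
            raise MeshFormatError(
                f"{path}: truncated or malformed element '{name}'") from exc
    else:
        off = 0
        try:
            for name, count, props in elements:
                recs = []
                for _ in range(count):
                    rec = {}
                    for p in props:
                        if p[0] == "list":
                            cfmt, csz = _PLY_TYPES[p[1]]
                            ifmt, isz = _PLY_TYPES[p[2]]
                            (n,) = struct.unpack_from("<" + cfmt, body, off)
                            off += csz
                            vals = struct.unpack_from("<" + ifmt * n, body, off)
                            off += isz * n
                            rec[p[3]] = [int(v) for v in vals]
                        else:
                            sfmt, ssz = _PLY_TYPES[p[1]]
                            (val,) = struct.unpack_from("<" + sfmt, body, off)
                            off += ssz
                            rec[p[2]] = float(val)
                    recs.append(rec)
                data[name] = recs
        except (struct.error, KeyError) as exc:
            raise MeshFormatError(
                f"{path}: truncated or malformed element '{name}'") from exc

    if "vertex" not in data:
        raise MeshFormatError(f"{path}: missing 'vertex' element")
    if "face" not in data:
        raise MeshFormatError(f"{path}: missing 'face' element")
    try:
        verts = np.array(
            [[r["x"], r["y"], r["z"]] for r in data["vertex"]], dtype=float)
    except KeyError as exc:
        raise MeshFormatError(f"{path}: vertex element lacks x/y/z") from exc
    faces = []
    for r in data["face"]:
        idx = r.get("vertex_indices", r.get("vertex_index"))
        if idx is None:
            raise MeshFormatError(
                f"{path}: face element lacks vertex_indices")
        faces.append(tuple(idx))
    mesh = Mesh(vertices=verts, faces=tuple(faces))
    mesh.validate()
    return mesh


def write_ply(mesh: Mesh, path: str | Path) -> None:
    """Write an ASCII PLY file (for inspection in external viewers)."""
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property float x", "property float y", "property float z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    for f in mesh.faces:
        lines.append(str(len(f)) + " " + " ".join(str(i) for i in f))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Edge graph / rotation system
# ---------------------------------------------------------------------------

#: An edge *instance*: (edge id, copy index).  Copy 1 exists only after
#: Eulerianization doubles the edge.
Instance = tuple[int, int]


@dataclass
class EdgeGraph:
    """Edge multigraph of a mesh plus the per-vertex rotation system.

    ``rotation[v]`` lists the incident edge instances of ``v`` in the
    cyclic geometric order obtained by walking adjacent faces; boundary
    vertices carry an open fan in the same order.  Every instance appears
    exactly once in each endpoint's rotation, so ``deg(v) ==
    len(rotation[v])``.
    """

    n_vertices: int
    edges: list[tuple[int, int]]        # edge id -> (u, v) with u < v
    multiplicity: list[int]             # edge id -> 1 or 2
    rotation: dict[int, list[Instance]]
    boundary_vertices: set[int] = field(default_factory=set)

    def degree(self, v: int) -> int:
        return len(self.rotation[v])

    def instances(self) -> list[Instance]:
        return [(e, c) for e, m in enumerate(self.multiplicity)
                for c in range(m)]

    def n_instances(self) -> int:
        return sum(self.multiplicity)

    def other(self, edge: int, v: int) -> int:
        a, b = self.edges[edge]
        if v == a:
            return b
        if v == b:
            return a
        raise ValueError(f"vertex {v} not an endpoint of edge {edge}")

    def validate(self) -> None:
        for v, rot in self.rotation.items():
            for inst in rot:
                if v not in self.edges[inst[0]]:
                    raise MeshValidationError(
                        f"rotation of {v} lists non-incident instance {inst}")
            if len(set(rot)) != len(rot):
                raise MeshValidationError(
                    f"rotation of {v} repeats an instance")
        for e, (a, b) in enumerate(self.edges):
            for c in range(self.multiplicity[e]):
                for v in (a, b):
                    if (e, c) not in self.rotation[v]:
                        raise MeshValidationError(
                            f"instance {(e, c)} missing from rotation of {v}")


def orient_faces(mesh: Mesh) -> Mesh:
    """Re-orient faces coherently (BFS over shared edges); fail if the
    surface is non-orientable."""
    nf = mesh.n_faces
    # edge -> list of (face, directed as (a, b))
    edge_use: dict[tuple[int, int], list[tuple[int, tuple[int, int]]]] = {}
    for fi, f in enumerate(mesh.faces):
        for i, a in enumerate(f):
            b = f[(i + 1) % len(f)]
            edge_use.setdefault((min(a, b), max(a, b)), []).append((fi, (a, b)))

    adj: dict[int, list[tuple[int, tuple[int, int], tuple[int, int]]]] = {
        fi: [] for fi in range(nf)}
    for uses in edge_use.values():
        if len(uses) == 2:
            (f1, d1), (f2, d2) = uses
            adj[f1].append((f2, d1, d2))
            adj[f2].append((f1, d2, d1))

    flip = [None] * nf  # type: list[bool | None]
    for root in range(nf):
        if flip[root] is not None:
            continue
        flip[root] = False
        stack = [root]
        while stack:
            fi = stack.pop()
            for fj, di, dj in adj[fi]:
                # coherent orientation: the shared edge runs in opposite
                # directions in the two faces
                same_dir = (di == dj)
                want = flip[fi] ^ same_dir
                if flip[fj] is None:
                    flip[fj] = want
                    stack.append(fj)
                elif flip[fj] != want:
                    raise OrientationError(
                        f"faces {fi} and {fj} cannot be oriented coherently "
                        "(non-orientable input)")
    faces = tuple(tuple(reversed(f)) if flip[fi] else f
                  for fi, f in enumerate(mesh.faces))
    return Mesh(vertices=mesh.vertices, faces=faces)


def build_edge_graph(mesh: Mesh) -> EdgeGraph:
    """Build the edge graph and rotation system of a validated mesh.

    The rotation at each vertex is derived by walking adjacent faces in
    the coherent orientation; each oriented face corner ``a -> v -> b``
    declares edge (v,b) the rotation successor of edge (v,a) at v.
    """
    mesh.validate()
    mesh = orient_faces(mesh)

    edge_id: dict[tuple[int, int], int] = {}
    edges: list[tuple[int, int]] = []
    for f in mesh.faces:
        for i, a in enumerate(f):
            b = f[(i + 1) % len(f)]
            key = (min(a, b), max(a, b))
            if key not in edge_id:
                edge_id[key] = len(edges)
                edges.append(key)

    succ: dict[int, dict[int, int]] = {v: {} for v in range(mesh.n_vertices)}
    for f in mesh.faces:
        n = len(f)
        for i, v in enumerate(f):
            a = f[(i - 1) % n]
            b = f[(i + 1) % n]
            e_in = edge_id[(min(v, a), max(v, a))]
            e_out = edge_id[(min(v, b), max(v, b))]
            if e_in in succ[v] and succ[v][e_in] != e_out:
                raise OrientationError(
                    f"inconsistent face walk at vertex {v}")
            succ[v][e_in] = e_out

    rotation: dict[int, list[Instance]] = {}
    boundary: set[int] = set()
    for v in range(mesh.n_vertices):
        sv = succ[v]
        if not sv:
            raise MeshValidationError(f"isolated vertex {v}")
        values = set(sv.values())
        starts = [e for e in sv if e not in values]
        if starts:  # open fan (boundary vertex)
            if len(starts) != 1:
                raise OrientationError(
                    f"vertex {v} has a disconnected edge fan")
            boundary.add(v)
            order = [starts[0]]
            while order[-1] in sv:
                order.append(sv[order[-1]])
        else:  # closed cycle; start at smallest edge id for determinism
            start = min(sv)
            order = [start]
            while True:
                nxt = sv[order[-1]]
                if nxt == start:
                    break
                order.append(nxt)
            if len(order) != len(sv):
                raise OrientationError(
                    f"vertex {v} has a disconnected edge fan")
        rotation[v] = [(e, 0) for e in order]

    graph = EdgeGraph(
        n_vertices=mesh.n_vertices,
        edges=edges,
        multiplicity=[1] * len(edges),
        rotation=rotation,
        boundary_vertices=boundary,
    )
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# Fixture meshes
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("triangle", "tetrahedron", "octahedron", "icosahedron",
                 "fan_polygon", "square_rod")


def _fan_polygon(n: int, scale: float) -> Mesh:
    ang = 2 * np.pi * np.arange(n) / n
    rim = np.stack([scale * np.cos(ang), scale * np.sin(ang),
                    np.zeros(n)], axis=1)
    verts = np.vstack([rim, [[0.0, 0.0, 0.0]]])
    faces = tuple((i, (i + 1) % n, n) for i in range(n))
    return Mesh(vertices=verts, faces=faces)


def _square_rod(segments: int, scale: float) -> Mesh:
    side = scale
    pitch = 2.4 * scale  # longitudinal edges ~2.4x the cross-section edges
    corners = np.array([[-0.5, -0.5], [0.5, -0.5], [0.5, 0.5], [-0.5, 0.5]])
    verts = []
    for k in range(segments + 1):
        for cx, cy in corners:
            verts.append([cx * side, cy * side, k * pitch])
    faces = []
    for k in range(segments):
        a = 4 * k
        b = 4 * (k + 1)
        for i in range(4):
            j = (i + 1) % 4
            faces.append((a + i, a + j, b + j))
            faces.append((a + i, b + j, b + i))
    faces.append((0, 2, 1))
    faces.append((0, 3, 2))
    t = 4 * segments
    faces.append((t + 0, t + 1, t + 2))
    faces.append((t + 0, t + 2, t + 3))
    return Mesh(vertices=np.array(verts, dtype=float), faces=tuple(faces))


def generate_fixture_mesh(name: str, scale: float = 1.0,
                          n: int = 5, segments: int = 3) -> Mesh:
    """Deterministic fixture meshes used throughout the test and design
    library: platonic solids, fan-triangulated 2D polygons and a
    triangulated square-cross-section rod.

    ``scale`` multiplies all coordinates (mesh units); ``n`` is the rim
    vertex count of ``fan_polygon``; ``segments`` the number of rod
    segments.
    """
    if scale <= 0 or n < 3 or segments < 1:
        raise ValueError("fixture parameters must be positive (n >= 3)")
    phi = (1 + np.sqrt(5)) / 2
    if name == "triangle":
        verts = scale * np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0]])
        mesh = Mesh(vertices=verts, faces=((0, 1, 2),))
    elif name == "tetrahedron":
        verts = scale * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        mesh = Mesh(vertices=verts, faces=(
            (0, 1, 2), (0, 3, 1), (0, 2, 3), (1, 3, 2)))
    elif name == "octahedron":
        verts = scale * np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
             [0, 0, 1], [0, 0, -1]], dtype=float)
        mesh = Mesh(vertices=verts, faces=(
            (0, 2, 4), (2, 1, 4), (1, 3, 4), (3, 0, 4),
            (2, 0, 5), (1, 2, 5), (3, 1, 5), (0, 3, 5)))
    elif name == "icosahedron":
        verts = scale * np.array(
            [[-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
             [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
             [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1]])
        mesh = Mesh(vertices=verts, faces=(
            (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
            (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
            (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
            (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1)))
    elif name == "fan_polygon":
        mesh = _fan_polygon(n, scale)
    elif name == "square_rod":
        mesh = _square_rod(segments, scale)
    else:
        raise ValueError(
            f"unknown fixture '{name}'; choose from {FIXTURE_NAMES}")
    mesh.validate()
    return mesh
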