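"""Edge lengths in base pairs, spring relaxation and the scaffold budget.

Mesh geometry is converted to integer helix lengths with the B-DNA rise
(0.34 nm/bp).  Because rounding to whole bases strains the geometry, the
vertex positions are then relaxed with a damped Hookean spring model
(each edge a spring with rest length ``length_bp * 0.34`` nm) until the
maximum relative strain falls below tolerance.  This is a deliberately
simple stand-in for a full physics engine: its contract is monotone
strain decrease and determinism, which is all downstream stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from .errors import ScaleError, WirebundleError
from .mesh import EdgeGraph, Mesh, build_edge_graph
from .routing import ATrail

__all__ = [
    "EdgeDesign", "StrainReport", "BudgetReport",
    "bp_to_nm", "nm_to_bp", "assign_edge_lengths", "relax",
    "check_scaffold_budget", "vertex_gap_nm", "scaffold_spacer_counts",
]


@dataclass(frozen=True)
class EdgeDesign:
    """Per-edge design state: integer length plus reinforcement flags."""
    edge: int
    length_bp: int
    length_nm: float
    reinforced: bool = False
    is_double: bool = False


def bp_to_nm(n: int) -> float:
    """Length in nm of ``n`` base pairs (rounded to 0.1 nm for display)."""
    if n < 0:
        raise ValueError("base count must be >= 0")
    return round(n * C.RISE_NM, 1)


def nm_to_bp(d: float) -> int:
    """Nearest whole-base length of a ``d`` nm helix."""
    if d < 0:
        raise ValueError("length must be >= 0")
    return int(round(d / C.RISE_NM))


def _edge_vectors(mesh: Mesh, graph: EdgeGraph) -> np.ndarray:
    p = mesh.vertices
    return np.array([p[b] - p[a] for a, b in graph.edges])


def assign_edge_lengths(mesh: Mesh, scale: float,
                        graph: EdgeGraph | None = None) -> list[EdgeDesign]:
    """Map geometric edge lengths to whole-base helix lengths.

    ``scale`` is nm per mesh unit.  Edge ids follow the edge graph's
    deterministic ordering.  An edge that rounds to zero bases raises
    :class:`ScaleError` naming the edge.
    """
    if scale <= 0:
        raise ScaleError("scale must be > 0")
    if graph is None:
        graph = build_edge_graph(mesh)
    designs = []
    lengths = np.linalg.norm(_edge_vectors(mesh, graph), axis=1) * scale
    for e, d in enumerate(lengths):
        bp = nm_to_bp(float(d))
        if bp < 1:
            raise ScaleError(
                f"edge {e} {graph.edges[e]} maps to 0 bp at scale {scale}")
        designs.append(EdgeDesign(edge=e, length_bp=bp,
                                  length_nm=bp_to_nm(bp)))
    return designs


@dataclass
class StrainReport:
    """Per-iteration total strain energy and the final residual."""
    series: list[float] = field(default_factory=list)
    iterations: int = 0
    max_relative_strain: float = 0.0
    converged: bool = False

    @property
    def initial(self) -> float:
        return self.series[0] if self.series else 0.0

    @property
    def final(self) -> float:
        return self.series[-1] if self.series else 0.0


def _strain_energy(pos: np.ndarray, edges: np.ndarray,
                   rest: np.ndarray) -> tuple[float, float]:
    vec = pos[edges[:, 1]] - pos[edges[:, 0]]
    length = np.linalg.norm(vec, axis=1)
    rel = (length - rest) / rest
    return float(np.sum(rel ** 2)), float(np.max(np.abs(rel)))


def relax(designs: list[EdgeDesign], mesh: Mesh, scale: float = 1.0,
          graph: EdgeGraph | None = None, max_iter: int = 500,
          tol: float = 1e-3) -> tuple[list[EdgeDesign], StrainReport,
                                      np.ndarray]:
    """Damped spring relaxation of vertex positions.

    Gradient descent with a halving line search on the total strain
    energy sum((l - r)^2 / r^2), so the reported series is non-increasing
    by construction.  Returns re-rounded designs, the strain report, and
    the relaxed vertex positions in nm.
    """
    if graph is None:
        graph = build_edge_graph(mesh)
    pos = mesh.vertices.astype(float) * scale
    if not np.all(np.isfinite(pos)):
        raise WirebundleError("non-finite vertex coordinates")
    edges = np.array(graph.edges, dtype=int)
    rest = np.array([d.length_bp for d in designs], dtype=float) * C.RISE_NM

    rep = StrainReport()
    energy, max_rel = _strain_energy(pos, edges, rest)
    rep.series.append(energy)
    rep.max_relative_strain = max_rel
    step = 0.1
    for it in range(max_iter):
        if max_rel < tol:
            rep.converged = True
            break
        vec = pos[edges[:, 1]] - pos[edges[:, 0]]
        length = np.linalg.norm(vec, axis=1)
        rel = (length - rest) / rest
        # gradient of sum(rel^2) wrt positions
        coef = (2 * rel / (rest * np.maximum(length, 1e-12)))[:, None]
        force = coef * vec
        grad = np.zeros_like(pos)
        np.add.at(grad, edges[:, 0], -force)
        np.add.at(grad, edges[:, 1], force)
        gnorm = np.linalg.norm(grad)
        if gnorm < 1e-15:
            rep.converged = max_rel < tol
            break
        trial_step = step
        improved = False
        for _ in range(40):
            cand = pos - trial_step * grad / gnorm
            cand_energy, cand_rel = _strain_energy(cand, edges, rest)
            if cand_energy < energy:
                pos, energy, max_rel = cand, cand_energy, cand_rel
                step = trial_step * 1.5
                improved = True
                break
            trial_step *= 0.5
        rep.series.append(energy)
        rep.iterations = it + 1
        rep.max_relative_strain = max_rel
        if not improved:
            break
    else:
        rep.converged = max_rel < tol
    if max_rel < tol:
        rep.converged = True

    # re-round base lengths from the relaxed geometry
    vec = pos[edges[:, 1]] - pos[edges[:, 0]]
    length = np.linalg.norm(vec, axis=1)
    out = []
    for d, l_nm in zip(designs, length):
        bp = max(1, nm_to_bp(float(l_nm)))
        out.append(replace(d, length_bp=bp, length_nm=bp_to_nm(bp)))
    return out, rep, pos


# ---------------------------------------------------------------------------
# Vertex gaps and the scaffold budget
# ---------------------------------------------------------------------------


def vertex_gap_nm(mesh: Mesh, graph: EdgeGraph, vertex: int,
                  edge_a: int, edge_b: int) -> float:
    """Estimated single-stranded gap (nm) between the ends of two edges
    meeting at a vertex: helix radius times the angle between them."""
    p = mesh.vertices
    va = p[graph.other(edge_a, vertex)] - p[vertex]
    vb = p[graph.other(edge_b, vertex)] - p[vertex]
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-12 or nb < 1e-12:
        return 0.0
    cosang = float(np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0))
    return C.HELIX_RADIUS_NM * float(np.arccos(cosang))


def _spacer_count(gap_nm: float) -> int:
    if gap_nm < 0:
        raise ValueError("gap must be >= 0")
    return int(min(C.MAX_T_SPACERS, max(0, round(gap_nm / C.SS_NT_NM))))


def scaffold_spacer_counts(trail: ATrail, mesh: Mesh,
                           graph: EdgeGraph) -> list[int]:
    """Unpaired scaffold bases inserted at each trail transition (one
    entry per step i, for the junction between step i and step i+1)."""
    counts = []
    n = len(trail.steps)
    for i, s in enumerate(trail.steps):
        t = trail.steps[(i + 1) % n]
        if s.edge == t.edge:
            counts.append(1)  # U-turn onto the parallel double-edge copy
        else:
            counts.append(_spacer_count(
                vertex_gap_nm(mesh, graph, s.head, s.edge, t.edge)))
    return counts


@dataclass
class BudgetReport:
    used: int
    available: int

    @property
    def ok(self) -> bool:
        return self.used <= self.available


def check_scaffold_budget(designs: list[EdgeDesign], trail: ATrail | None,
                          reinforced: set[int] | None = None,
                          scaffold_length: int = C.DEFAULT_SCAFFOLD_LENGTH,
                          spacer_counts: list[int] | None = None,
                          ) -> BudgetReport:
    """Count the scaffold bases a design consumes against the budget.

    Scaffold-traversed bases are the main helices (each trail step once,
    so doubled edges count twice), the two loop helices of every
    reinforced edge, and the vertex spacer bases.  Mini-scaffold bases
    are synthesized separately and are NOT counted.
    """
    from .reinforce import loop_span  # local import to avoid a cycle

    if designs and trail is None:
        raise WirebundleError("a trail is required for a non-empty design")
    used = 0
    if trail is not None:
        by_edge = {d.edge: d for d in designs}
        for s in trail.steps:
            used += by_edge[s.edge].length_bp
        reinforced = reinforced if reinforced is not None else {
            d.edge for d in designs if d.reinforced}
        for e in reinforced:
            lo, hi = loop_span(by_edge[e].length_bp)
            used += 2 * (hi - lo + 1)
        if spacer_counts is None:
            spacer_counts = [2] * len(trail.steps)
        used += sum(spacer_counts)
    return BudgetReport(used=used, available=scaffold_length)
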