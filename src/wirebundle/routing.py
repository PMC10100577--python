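"""Scaffold routing: Eulerianization by edge doubling and A-trail search.

An A-trail is an Eulerian circuit in which every pair of consecutive
edges is adjacent in the cyclic rotation around their shared vertex, so
the scaffold never crosses itself at a vertex.  Meshes whose vertices
have odd degree first receive "double edges" (a second parallel helix)
chosen as a minimum T-join, which makes every degree even while adding
as few helices as possible.

A-trail existence is NP-hard in general; the meshes handled here are
small, so the search is a depth-first backtracking in which at each
vertex visit only the two rotation neighbours of the incoming edge are
candidate continuations.  The search is deterministic: candidate order
is fixed, and the seed permutes the starting edge only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import NoATrailError, RoutingError
from .mesh import EdgeGraph, Instance

__all__ = [
    "TrailStep", "ATrail", "ValidationReport",
    "eulerianize", "minimum_doubling_sets", "apply_doubling",
    "find_atrail", "validate_atrail", "route",
]


@dataclass(frozen=True)
class TrailStep:
    """One directed edge instance of the scaffold circuit."""
    edge: int
    copy: int
    tail: int
    head: int


@dataclass
class ATrail:
    """The scaffold circuit: an ordered closed walk over every edge
    instance, obeying the rotation-neighbour constraint."""
    steps: list[TrailStep]
    start: int

    def to_json_obj(self) -> dict:
        return {
            "start": self.start,
            "steps": [[s.edge, s.copy, s.tail, s.head] for s in self.steps],
        }

    @classmethod
    def from_json_obj(cls, obj: dict) -> "ATrail":
        return cls(steps=[TrailStep(*s) for s in obj["steps"]],
                   start=obj["start"])


@dataclass
class ValidationReport:
    ok: bool
    violations: list[tuple[int, int, str]] = field(default_factory=list)


def _nx_graph(graph: EdgeGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_vertices))
    for e, (a, b) in enumerate(graph.edges):
        g.add_edge(a, b, eid=e)
    return g


def _check_connected(graph: EdgeGraph) -> None:
    g = _nx_graph(graph)
    used = [v for v in g.nodes if g.degree(v) > 0]
    if used and not nx.is_connected(g.subgraph(used)):
        raise RoutingError("edge graph is disconnected")


def apply_doubling(graph: EdgeGraph, doubled: list[int]) -> EdgeGraph:
    """Return a new graph with the given edges doubled; each new copy is
    inserted immediately adjacent to its sibling in both endpoint
    rotations (a double edge is physically a parallel helix pair)."""
    mult = list(graph.multiplicity)
    rotation = {v: list(rot) for v, rot in graph.rotation.items()}
    for e in doubled:
        if mult[e] != 1:
            raise RoutingError(f"edge {e} already doubled")
        mult[e] = 2
        for v in graph.edges[e]:
            idx = rotation[v].index((e, 0))
            rotation[v].insert(idx + 1, (e, 1))
    out = EdgeGraph(
        n_vertices=graph.n_vertices,
        edges=list(graph.edges),
        multiplicity=mult,
        rotation=rotation,
        boundary_vertices=set(graph.boundary_vertices),
    )
    out.validate()
    return out


def _odd_vertices(graph: EdgeGraph) -> list[int]:
    return [v for v in range(graph.n_vertices)
            if v in graph.rotation and graph.degree(v) % 2 == 1]


def _matchings(items: list[int], dist: dict):
    """Yield all perfect matchings of ``items`` as lists of pairs."""
    if not items:
        yield []
        return
    first = items[0]
    for j in range(1, len(items)):
        second = items[j]
        rest = items[1:j] + items[j + 1:]
        for sub in _matchings(rest, dist):
            yield [(first, second)] + sub


def minimum_doubling_sets(graph: EdgeGraph, limit: int = 16):
    """Yield up to ``limit`` distinct minimum-size doubling sets (edge-id
    lists) that make every vertex degree even.

    Each set is the symmetric difference of shortest paths joining a
    minimum-weight perfect matching of the odd-degree vertices (a minimum
    T-join), so its size is provably minimal.
    """
    odd = _odd_vertices(graph)
    if not odd:
        yield []
        return
    g = _nx_graph(graph)
    dist = {}
    paths = {}
    for a in odd:
        lengths, ps = nx.single_source_dijkstra(g, a)
        for b in odd:
            if b != a:
                dist[(a, b)] = lengths[b]
                paths[(a, b)] = ps[b]

    best = None
    seen: set[frozenset] = set()
    count = 0
    # enumerate matchings in generation order, keeping those at min weight
    candidates = []
    for m in _matchings(odd, dist):
        w = sum(dist[p] for p in m)
        candidates.append((w, m))
    candidates.sort(key=lambda t: t[0])
    best = candidates[0][0] if candidates else 0
    for w, m in candidates:
        if w > best or count >= limit:
            break
        edge_count: dict[int, int] = {}
        for a, b in m:
            path = paths[(a, b)]
            for u, v in zip(path, path[1:]):
                eid = g.edges[u, v]["eid"]
                edge_count[eid] = edge_count.get(eid, 0) + 1
        dset = frozenset(e for e, c in edge_count.items() if c % 2 == 1)
        if dset not in seen:
            seen.add(dset)
            count += 1
            yield sorted(dset)


def eulerianize(graph: EdgeGraph) -> tuple[EdgeGraph, list[int]]:
    """Make the graph Eulerian by doubling a minimum set of edges.

    Returns the new multigraph and the list of doubled edge ids.  Graphs
    that are already even are returned unchanged (idempotent).
    """
    _check_connected(graph)
    doubled = next(minimum_doubling_sets(graph, limit=1))
    if not doubled:
        return graph, []
    return apply_doubling(graph, doubled), doubled


# ---------------------------------------------------------------------------
# A-trail search
# ---------------------------------------------------------------------------


def find_atrail(graph: EdgeGraph, seed: int = 0,
                max_states: int = 5_000_000) -> ATrail:
    """Depth-first backtracking search for an A-trail.

    At each vertex visit only the two rotation neighbours of the incoming
    instance are candidate continuations; candidate order is fixed, and
    ``seed`` selects the starting edge instance, so results are
    deterministic.  Raises :class:`NoATrailError` (carrying the explored
    state count) when the search space is exhausted or the state cap hit.
    """
    odd = _odd_vertices(graph)
    if odd:
        raise RoutingError(f"graph is not Eulerian; odd-degree vertices {odd}")
    insts = graph.instances()
    if not insts:
        raise RoutingError("graph has no edges")
    n = len(insts)
    inst_id = {inst: i for i, inst in enumerate(insts)}
    pos = {v: {inst: i for i, inst in enumerate(rot)}
           for v, rot in graph.rotation.items()}

    first = insts[seed % n]
    u, v = graph.edges[first[0]]
    start = u
    used = [False] * n
    used[inst_id[first]] = True
    path = [TrailStep(first[0], first[1], u, v)]
    explored = 0

    def adjacent(vv: int, a: Instance, b: Instance) -> bool:
        rot = graph.rotation[vv]
        if len(rot) <= 2:
            return True
        d = abs(pos[vv][a] - pos[vv][b])
        return d == 1 or d == len(rot) - 1

    def dfs(cur: int, incoming: Instance, depth: int) -> bool:
        nonlocal explored
        explored += 1
        if explored > max_states:
            raise NoATrailError(
                f"A-trail search state cap ({max_states}) exceeded",
                explored=explored)
        if depth == n:
            return cur == start and adjacent(start, incoming, first)
        rot = graph.rotation[cur]
        k = len(rot)
        i = pos[cur][incoming]
        cands = []
        for off in (1, k - 1):
            cand = rot[(i + off) % k]
            if cand not in cands:
                cands.append(cand)
        for cand in cands:
            cid = inst_id[cand]
            if used[cid]:
                continue
            nxt = graph.other(cand[0], cur)
            used[cid] = True
            path.append(TrailStep(cand[0], cand[1], cur, nxt))
            if dfs(nxt, cand, depth + 1):
                return True
            path.pop()
            used[cid] = False
        return False

    if dfs(v, first, 1):
        return ATrail(steps=list(path), start=start)
    raise NoATrailError(
        f"no A-trail exists for this rotation system (explored {explored} "
        "states)", explored=explored)


def validate_atrail(graph: EdgeGraph, trail: ATrail) -> ValidationReport:
    """Independent checker of the three A-trail invariants.

    Returns a report; ``violations`` entries are (step position, vertex,
    rule) tuples.
    """
    rep = ValidationReport(ok=True)
    steps = trail.steps
    if not steps:
        rep.ok = False
        rep.violations.append((0, trail.start, "empty trail"))
        return rep
    n = len(steps)
    # closed walk
    for i, s in enumerate(steps):
        t = steps[(i + 1) % n]
        if s.head != t.tail:
            rep.violations.append((i, s.head, "closed-walk"))
        if {s.tail, s.head} != set(graph.edges[s.edge]):
            rep.violations.append((i, s.tail, "step-endpoint-mismatch"))
    # coverage
    want = set(graph.instances())
    got = [(s.edge, s.copy) for s in steps]
    if len(set(got)) != len(got):
        rep.violations.append((0, trail.start, "instance-repeated"))
    missing = want - set(got)
    extra = set(got) - want
    if missing or extra:
        rep.violations.append((0, trail.start, "coverage"))
    # neighbour constraint at every junction (including the wrap-around)
    pos = {v: {inst: i for i, inst in enumerate(rot)}
           for v, rot in graph.rotation.items()}
    for i, s in enumerate(steps):
        t = steps[(i + 1) % n]
        v = s.head
        a, b = (s.edge, s.copy), (t.edge, t.copy)
        rot = graph.rotation.get(v, [])
        if a not in pos.get(v, {}) or b not in pos.get(v, {}):
            rep.violations.append((i, v, "instance-not-at-vertex"))
            continue
        if len(rot) > 2:
            d = abs(pos[v][a] - pos[v][b])
            if d != 1 and d != len(rot) - 1:
                rep.violations.append((i, v, "rotation-neighbor"))
    rep.ok = not rep.violations
    return rep


def route(graph: EdgeGraph, seed: int = 0, max_doubling_retries: int = 8,
          max_states: int = 5_000_000) -> tuple[ATrail, EdgeGraph, list[int]]:
    """Eulerianize then find an A-trail, retrying alternative minimum
    doubling sets if the first placement admits none.

    Returns (trail, eulerianized graph, doubled edge ids).
    """
    _check_connected(graph)
    last: NoATrailError | None = None
    for dset in minimum_doubling_sets(graph, limit=max_doubling_retries):
        g2 = apply_doubling(graph, dset) if dset else graph
        try:
            trail = find_atrail(g2, seed=seed, max_states=max_states)
            return trail, g2, list(dset)
        except NoATrailError as exc:
            last = exc
    raise NoATrailError(
        "no A-trail found for any minimum doubling placement "
        f"(last search explored {last.explored if last else 0} states)",
        explored=last.explored if last else 0)
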