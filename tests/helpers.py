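"""Independent oracles used by the test suite.

These deliberately re-derive results from first principles (exhaustive
enumeration, direct counting) rather than reusing the package's search
or bookkeeping code paths.
"""

from __future__ import annotations

from itertools import combinations

from wirebundle.mesh import EdgeGraph


def atrail_exists_bruteforce(graph: EdgeGraph) -> bool:
    """Exhaustive check whether ANY A-trail exists: try every start and
    enumerate every closed walk that uses each edge instance once with
    consecutive edges rotation-adjacent (including the wrap-around)."""
    insts = graph.instances()
    n = len(insts)
    if n == 0:
        return False
    pos = {v: {inst: i for i, inst in enumerate(rot)}
           for v, rot in graph.rotation.items()}

    def neighbors(v, inst):
        rot = graph.rotation[v]
        k = len(rot)
        if k <= 2:
            return [x for x in rot if x != inst] or list(rot)
        i = pos[v][inst]
        return [rot[(i + 1) % k], rot[(i - 1) % k]]

    def adjacent(v, a, b):
        rot = graph.rotation[v]
        if len(rot) <= 2:
            return True
        d = abs(pos[v][a] - pos[v][b])
        return d in (1, len(rot) - 1)

    first = insts[0]
    u, v0 = graph.edges[first[0]]
    used = {first}

    def rec(cur, incoming):
        if len(used) == n:
            return cur == u and adjacent(u, incoming, first)
        for cand in neighbors(cur, incoming):
            if cand in used:
                continue
            used.add(cand)
            if rec(graph.other(cand[0], cur), cand):
                return True
            used.remove(cand)
        return False

    return rec(v0, first)


def min_doubling_size_bruteforce(graph: EdgeGraph, max_size: int = 6) -> int:
    """Smallest k such that doubling some k edges makes every degree
    even, by exhaustive search over edge subsets."""
    odd_mask = 0
    for v in range(graph.n_vertices):
        if graph.degree(v) % 2 == 1:
            odd_mask |= 1 << v
    if odd_mask == 0:
        return 0
    edge_masks = [(1 << a) | (1 << b) for a, b in graph.edges]
    for k in range(1, max_size + 1):
        for combo in combinations(edge_masks, k):
            m = 0
            for em in combo:
                m ^= em
            if m == odd_mask:
                return k
    raise AssertionError(f"no doubling of size <= {max_size} found")


def staple_side_occupancy(model) -> dict:
    """Direct per-base staple-side count over every staple step."""
    counts: dict[tuple[int, int], int] = {}
    for st in model.staples:
        for s in st.steps:
            if s.helix is None:
                continue
            key = (model.helix_of[s.helix], s.base)
            counts[key] = counts.get(key, 0) + 1
    return counts


def scaffold_side_occupancy(model) -> dict:
    counts: dict[tuple[int, int], int] = {}
    for s in model.scaffold:
        if s.helix >= 0:
            counts[(s.helix, s.base)] = counts.get((s.helix, s.base), 0) + 1
    for oligo in model.minis:
        for s in oligo:
            counts[(s.helix, s.base)] = counts.get((s.helix, s.base), 0) + 1
    return counts
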