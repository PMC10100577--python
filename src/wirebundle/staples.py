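"""Staple design: modular bundle staples and vertex staples.

Two staple classes fold the scaffold:

* **bundle** staples connect helices within an edge.  Their routing is
  modular: each 32-base super-period of a four-helix bundle carries four
  interior staples of exactly 32 bases with a single 16-base seed and two
  8-base domains, weaving between lattice-adjacent helices at admissible
  crossover columns.  Regions left at the bundle ends are covered by
  terminal staples (flagged non-interior) of 14-60 bases.
* **vertex** staples clamp the ends of two edges adjacent in the vertex
  rotation, one arm on each edge, with unpaired T spacers between the
  arms to bridge the inter-helix gap.  Their total length is kept within
  30-60 bases; edges too short to host arms of their own are spanned
  pass-through by a single staple anchored on their rotation neighbours.

Strand bookkeeping uses a canonical per-edge frame: the scaffold side of
the ring (main, loopA, loopB, mini/main2) runs (+,-,+,-) along the base
axis and staples run antiparallel to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import constants as C
from .errors import StapleDesignError
from .layout import EdgeDesign, _spacer_count
from .mesh import EdgeGraph
from .reinforce import BundleLayout

__all__ = [
    "StapleStep", "Staple", "compute_t_spacers",
    "design_bundle_staples", "design_edge_staples", "design_vertex_staples",
    "design_staples",
]

#: helix reference: (edge id, role); role in main/main2/loopA/loopB/mini
HelixRef = tuple[int, str]

#: staple-side walk direction per role (scaffold side is the opposite)
STAPLE_DIR = {"main": -1, "loopA": +1, "loopB": -1, "mini": +1, "main2": +1}
SCAFFOLD_DIR = {r: -d for r, d in STAPLE_DIR.items()}


@dataclass(frozen=True)
class StapleStep:
    helix: HelixRef | None  # None for an unpaired T spacer
    base: int               # -1 for spacers
    paired: bool


@dataclass
class Staple:
    steps: list[StapleStep]
    cls: str                 # "vertex" | "bundle"
    interior: bool = False
    name: str = ""

    @property
    def length(self) -> int:
        return len(self.steps)

    @property
    def seed_length(self) -> int:
        """Longest contiguous single-helix paired domain."""
        best = run = 0
        prev: HelixRef | None = None
        for s in self.steps:
            if s.helix is not None and s.helix == prev:
                run += 1
            elif s.helix is not None:
                run = 1
            else:
                run = 0
            prev = s.helix
            best = max(best, run)
        return best

    def domains(self) -> list[tuple[HelixRef, int, int]]:
        """Contiguous helix domains as (helix, lo, hi) inclusive."""
        out: list[tuple[HelixRef, int, int]] = []
        for s in self.steps:
            if s.helix is None:
                continue
            if out and out[-1][0] == s.helix and (
                    abs(s.base - out[-1][2]) == 1 or
                    abs(s.base - out[-1][1]) == 1):
                h, lo, hi = out[-1]
                out[-1] = (h, min(lo, s.base), max(hi, s.base))
            else:
                out.append((s.helix, s.base, s.base))
        return out


def compute_t_spacers(gap_nm: float) -> int:
    """Unpaired T bases bridging a ``gap_nm`` single-stranded gap:
    round(gap / 0.4 nm) clamped to [0, 5]."""
    return _spacer_count(gap_nm)


def _walk(helix: HelixRef, lo: int, hi: int, direction: int,
          paired: bool = True) -> list[StapleStep]:
    """Steps covering [lo, hi) in the given direction."""
    rng = range(lo, hi) if direction > 0 else range(hi - 1, lo - 1, -1)
    return [StapleStep(helix, b, paired) for b in rng]


def _spacers(n: int) -> list[StapleStep]:
    return [StapleStep(None, -1, False) for _ in range(n)]


# ---------------------------------------------------------------------------
# Bundle staples
# ---------------------------------------------------------------------------


def _interior_period(edge: int, ring: tuple[str, ...], p0: int) -> list[Staple]:
    """The four 32-base interior staples of one super-period [p0, p0+32).

    Offsets are chosen so that every helix's four 8-base slots are
    covered exactly once per period and all crossovers fall on admissible
    columns (0 and 7 mod 8)."""
    r0, r1, r2, r3 = [(edge, r) for r in ring]
    d = {role: STAPLE_DIR[role] for role in ring}
    P = p0
    specs = [
        [(r3, P + 8, P + 16), (r0, P, P + 16), (r1, P, P + 8)],
        [(r0, P + 16, P + 24), (r1, P + 16, P + 32), (r2, P + 24, P + 32)],
        [(r1, P + 8, P + 16), (r2, P, P + 16), (r3, P, P + 8)],
        [(r2, P + 16, P + 24), (r3, P + 16, P + 32), (r0, P + 24, P + 32)],
    ]
    staples = []
    for k, doms in enumerate(specs):
        steps: list[StapleStep] = []
        for h, lo, hi in doms:
            steps.extend(_walk(h, lo, hi, d[h[1]]))
        staples.append(Staple(steps=steps, cls="bundle", interior=True,
                              name=f"e{edge}_int{p0}_{k}"))
    return staples


def _even_pieces(width: int, target: int) -> list[int]:
    """Split ``width`` into near-equal pieces of roughly ``target`` bases,
    each within [TERMINAL_STAPLE_MIN, 60]."""
    n = max(1, round(width / target))
    while width / n > C.VERTEX_STAPLE_MAX - 4:  # slack for boundary nudges
        n += 1
    while n > 1 and width / n < C.TERMINAL_STAPLE_MIN:
        n -= 1
    base, rem = divmod(width, n)
    return [base + 1] * rem + [base] * (n - rem)


def _segments(lo: int, hi: int, pieces: list[int],
              forbidden: set[int]) -> list[tuple[int, int]]:
    """Column segments from piece widths, nudging internal boundaries off
    forbidden nick columns (scaffold crossovers, end-loops)."""
    bounds = []
    at = lo
    for w in pieces[:-1]:
        at += w
        bounds.append(at)
    nudged = []
    prev = lo
    for b in bounds:
        while b in forbidden or (b - 1) in forbidden:
            b += 1
        if b <= prev or b >= hi:
            raise StapleDesignError(
                f"cannot place a staple boundary clear of crossovers in "
                f"[{lo},{hi})")
        nudged.append(b)
        prev = b
    cols = [lo] + nudged + [hi]
    return list(zip(cols, cols[1:]))


def _single_domain_staples(edge: int, role: str, lo: int, hi: int,
                           tag: str,
                           forbidden: set[int] | None = None) -> list[Staple]:
    pieces = _even_pieces(hi - lo, C.STAPLE_MODULE)
    out = []
    for i, (a, b) in enumerate(_segments(lo, hi, pieces, forbidden or set())):
        steps = _walk((edge, role), a, b, STAPLE_DIR[role])
        out.append(Staple(steps=steps, cls="bundle", interior=False,
                          name=f"e{edge}_{tag}{i}"))
    return out


def design_bundle_staples(
        bundle: BundleLayout,
        reserves: dict[tuple[str, int], int] | None = None,
) -> tuple[list[Staple], dict[tuple[str, int], int]]:
    """Staples covering the four helices of one bundle.

    ``reserves`` maps (role, end) -> bases of the scaffold-carrying
    helix ends already claimed by vertex staple arms (role "main" or
    "main2", end 0 = base-0 side).  Returns the staples plus *arm
    extensions*: sub-14-base main-helix remainders that the caller must
    merge into the adjacent vertex arm, keyed the same way.
    """
    reserves = reserves or {}
    L = bundle.length_bp
    ring = bundle.ring
    e = bundle.edge

    ranges: dict[str, tuple[int, int]] = {}
    for role in ring:
        if role in ("main", "main2"):
            ranges[role] = (reserves.get((role, 0), 0),
                            L - reserves.get((role, 1), 0))
        elif role == "mini":
            ranges[role] = (0, L)
        else:
            ranges[role] = (bundle.loop_lo, bundle.loop_hi + 1)

    win_lo = max(r[0] for r in ranges.values())
    win_hi = min(r[1] for r in ranges.values())
    t0 = -(-win_lo // C.STAPLE_MODULE) * C.STAPLE_MODULE
    n_periods = max(0, (win_hi - t0) // C.STAPLE_MODULE)
    t1 = t0 + n_periods * C.STAPLE_MODULE

    staples: list[Staple] = []
    for p in range(n_periods):
        staples.extend(_interior_period(e, ring, t0 + p * C.STAPLE_MODULE))

    def leftovers(role: str) -> list[tuple[int, int]]:
        lo, hi = ranges[role]
        if lo >= hi:
            return []
        if n_periods == 0:
            return [(lo, hi)]
        out = []
        if lo < t0:
            out.append((lo, t0))
        if t1 < hi:
            out.append((t1, hi))
        return out

    # forbidden nick columns: the scaffold double crossover and end-loops
    c0 = bundle.scaffold_site
    forbid = {"main": {c0, c0 + 1},
              "loopA": {c0, c0 + 1, bundle.loop_lo, bundle.loop_hi},
              "loopB": {bundle.loop_lo, bundle.loop_hi},
              "mini": set(), "main2": set()}

    # loop caps: pair identical loopA/loopB leftover intervals
    for (alo, ahi) in leftovers("loopA"):
        staples.extend(_cap_staples(e, alo, ahi, bundle,
                                    forbid["loopA"] | forbid["loopB"]))

    # fourth helix (mini or second main)
    extensions: dict[tuple[str, int], int] = {}
    r3 = ring[3]
    for (lo, hi) in leftovers(r3):
        _cover_scaffold_helix(staples, extensions, e, r3, lo, hi,
                              ranges[r3], t0, t1, n_periods, forbid[r3])

    for (lo, hi) in leftovers("main"):
        _cover_scaffold_helix(staples, extensions, e, "main", lo, hi,
                              ranges["main"], t0, t1, n_periods,
                              forbid["main"])

    _check_bundle_nicks(staples, forbid)
    return staples, extensions


def _cap_staples(edge: int, lo: int, hi: int, bundle: BundleLayout,
                 forbidden: set[int]) -> list[Staple]:
    """Terminal staples closing the loop pair over columns [lo, hi).

    A segment whose lowest column is the loop's end-loop position must
    *cross* between the loop helices there rather than nick, so its walk
    starts on loopB; likewise no nick may fall on the upper end-loop
    column, so a segment reaching it keeps the default loopA-first walk
    (nicks at its low column).  A single segment containing both
    end-loop columns is split in two.
    """
    w = hi - lo
    if w == 0:
        return []
    n = -(-2 * w // (C.VERTEX_STAPLE_MAX - 4))  # slack for boundary nudges
    spans_both = (lo == bundle.loop_lo) and (hi - 1 == bundle.loop_hi)
    if spans_both and n == 1:
        n = 2
    base, rem = divmod(w, n)
    pieces = [base + 1] * rem + [base] * (n - rem)
    out = []
    for (a, b) in _segments(lo, hi, pieces, forbidden):
        if a == bundle.loop_lo:
            steps = _walk((edge, "loopB"), a, b, STAPLE_DIR["loopB"])
            steps += _walk((edge, "loopA"), a, b, STAPLE_DIR["loopA"])
        else:
            steps = _walk((edge, "loopA"), a, b, STAPLE_DIR["loopA"])
            steps += _walk((edge, "loopB"), a, b, STAPLE_DIR["loopB"])
        out.append(Staple(steps=steps, cls="bundle", interior=False,
                          name=f"e{edge}_cap{a}"))
    return out


def _check_bundle_nicks(staples: list[Staple], forbid: dict) -> None:
    """No bundle staple may begin or end on a scaffold crossover or
    end-loop column of its helix, and lengths stay within [14, 60]."""
    for st in staples:
        if st.cls != "bundle":
            continue
        if not (C.TERMINAL_STAPLE_MIN <= st.length <= C.VERTEX_STAPLE_MAX):
            raise StapleDesignError(
                f"bundle staple {st.name} length {st.length} outside "
                f"[{C.TERMINAL_STAPLE_MIN}, {C.VERTEX_STAPLE_MAX}]")
        for s in (st.steps[0], st.steps[-1]):
            if s.helix is not None and s.base in forbid.get(s.helix[1], ()):
                raise StapleDesignError(
                    f"staple {st.name} nick at {s.helix}:{s.base} coincides "
                    "with a scaffold crossover")


def _cover_scaffold_helix(staples, extensions, edge, role, lo, hi,
                          full_range, t0, t1, n_periods,
                          forbidden: set[int] | None = None) -> None:
    """Cover a leftover interval on a scaffold-carrying helix.

    Mini intervals are always wide enough for standalone staples; main /
    main2 remainders below 14 bases are merged into the neighbouring
    interior staple when tiling exists, otherwise handed back as vertex
    arm extensions."""
    w = hi - lo
    if w == 0:
        return
    if w >= C.TERMINAL_STAPLE_MIN:
        staples.extend(_single_domain_staples(edge, role, lo, hi,
                                              f"{role}_t{lo}_", forbidden))
        return
    if role == "mini":
        raise StapleDesignError(
            f"mini remainder of {w} bases on edge {edge} (unexpected)")
    if n_periods > 0:
        href = (edge, role)
        if hi == t0:  # left remainder: extend the staple starting at t0
            _extend_staple(staples, href, t0, lo, hi, at_start=True)
        elif lo == t1:  # right remainder
            _extend_staple(staples, href, t1 - 1, lo, hi, at_start=False)
        else:
            raise StapleDesignError(
                f"stranded {w}-base remainder on edge {edge} {role}")
        return
    # no tiling on this edge: merge into a vertex arm
    end = 0 if lo == full_range[0] else 1
    extensions[(role, end)] = extensions.get((role, end), 0) + w


def _extend_staple(staples: list[Staple], helix: HelixRef, anchor: int,
                   lo: int, hi: int, at_start: bool) -> None:
    """Grow the interior staple whose domain touches ``anchor`` on
    ``helix`` so that it also covers [lo, hi); it stops being interior."""
    for st in staples:
        if st.cls != "bundle" or st.length + (hi - lo) > C.VERTEX_STAPLE_MAX:
            continue
        doms = st.domains()
        for h, dlo, dhi in doms:
            if h != helix:
                continue
            if at_start and dlo == anchor:
                extra = _walk(helix, lo, hi, STAPLE_DIR[helix[1]])
                # the main domain is walked -; new bases continue past dlo
                st.steps = _insert_adjacent(st.steps, helix, extra)
                st.interior = False
                return
            if not at_start and dhi == anchor:
                extra = _walk(helix, lo, hi, STAPLE_DIR[helix[1]])
                st.steps = _insert_adjacent(st.steps, helix, extra)
                st.interior = False
                return
    raise StapleDesignError(
        f"no interior staple adjacent to remainder at {helix}:{anchor}")


def _insert_adjacent(steps: list[StapleStep], helix: HelixRef,
                     extra: list[StapleStep]) -> list[StapleStep]:
    """Splice ``extra`` (already walked in helix direction) next to the
    existing domain on ``helix`` so base indices stay contiguous."""
    idxs = [i for i, s in enumerate(steps) if s.helix == helix]
    first, last = idxs[0], idxs[-1]
    if abs(extra[-1].base - steps[first].base) == 1:
        return steps[:first] + extra + steps[first:]
    if abs(extra[0].base - steps[last].base) == 1:
        return steps[:last + 1] + extra + steps[last + 1:]
    raise StapleDesignError("extension does not abut the staple domain")


def design_edge_staples(
        design: EdgeDesign,
        reserves: dict[tuple[str, int], int] | None = None,
) -> tuple[list[Staple], dict[tuple[str, int], int]]:
    """Modular staples for a NON-reinforced edge (one or two plain
    helices); same return convention as :func:`design_bundle_staples`."""
    reserves = reserves or {}
    L = design.length_bp
    roles = ("main", "main2") if design.is_double else ("main",)
    staples: list[Staple] = []
    extensions: dict[tuple[str, int], int] = {}
    for role in roles:
        lo = reserves.get((role, 0), 0)
        hi = L - reserves.get((role, 1), 0)
        w = hi - lo
        if w == 0:
            continue
        if w >= C.TERMINAL_STAPLE_MIN:
            staples.extend(_single_domain_staples(design.edge, role, lo, hi,
                                                  f"{role}_m"))
        else:
            extensions[(role, 0)] = w  # resolved against either arm later
    return staples, extensions


# ---------------------------------------------------------------------------
# Vertex staples
# ---------------------------------------------------------------------------


@dataclass
class _End:
    """One edge-instance end at a vertex, with its arm allocation state."""
    edge: int
    copy: int
    end: int       # 0 = base-0 side, 1 = base-(L-1) side
    vertex: int
    length: int
    capacity: int
    arms: list[list] = field(default_factory=list)  # [staple plan, lo, hi]

    @property
    def role(self) -> str:
        return "main" if self.copy == 0 else "main2"

    @property
    def allocated(self) -> int:
        return sum(hi - lo for _, lo, hi in self.arms)

    def alloc(self, plan: "_Plan", width: int) -> tuple[int, int]:
        if self.end == 0:
            lo = self.allocated
            hi = lo + width
        else:
            hi = self.length - self.allocated
            lo = hi - width
        self.arms.append([plan, lo, hi])
        self.capacity -= 1
        return lo, hi


@dataclass
class _Plan:
    """A planned vertex staple: ordered (end, lo, hi) arm slots plus the
    spacer counts inserted after each arm (0 after the last)."""
    arms: list[tuple[_End, int, int]] = field(default_factory=list)
    spacers: list[int] = field(default_factory=list)
    passthrough: HelixRef | None = None


def _capacity(length_bp: int) -> int:
    if length_bp >= 2 * C.STAPLE_MODULE + 2 * C.ARM_DEFAULT:
        return 2
    if length_bp >= 2 * C.ARM_DEFAULT + C.LOOP_END_MARGIN:
        return 1
    return 0


def design_vertex_staples(graph: EdgeGraph, vertex: int,
                          designs: list[EdgeDesign],
                          gap_fn=None) -> list[Staple]:
    """Vertex staples of a single vertex with default arm allocation.

    Convenience wrapper over the global designer restricted to one
    vertex; pass-through edges are not handled here (they need both of
    their vertices)."""
    ends, plans = _plan_vertex_staples(graph, designs, gap_fn,
                                       vertices=[vertex])
    return [_materialize(p, i) for i, p in enumerate(plans)]


def _plan_vertex_staples(graph: EdgeGraph, designs: list[EdgeDesign],
                         gap_fn=None, vertices=None):
    """Plan arm allocations for vertex staples.

    Returns (ends map, plans).  ``gap_fn(vertex, edge_a, edge_b) -> int``
    gives the T spacer count for a junction (default 2)."""
    if gap_fn is None:
        gap_fn = lambda v, a, b: 2  # noqa: E731
    by_edge = {d.edge: d for d in designs}
    ends: dict[tuple[int, int, int], _End] = {}
    for v, rot in graph.rotation.items():
        for (e, c) in rot:
            a, b = graph.edges[e]
            endidx = 0 if v == a else 1
            L = by_edge[e].length_bp
            ends[(e, c, endidx)] = _End(
                edge=e, copy=c, end=endidx, vertex=v, length=L,
                capacity=_capacity(L))

    if vertices is None:
        vertices = sorted(graph.rotation)
        handle_pass = True
    else:
        handle_pass = False

    plans: list[_Plan] = []

    def end_at(v: int, inst) -> _End:
        e, c = inst
        a, b = graph.edges[e]
        return ends[(e, c, 0 if v == a else 1)]

    # pass-through staples for edges too short to host arms
    if handle_pass:
        for e, d in sorted(by_edge.items()):
            for c in range(graph.multiplicity[e]):
                if _capacity(d.length_bp) > 0:
                    continue
                plan = _Plan(passthrough=(e, "main" if c == 0 else "main2"))
                arm_ends = []
                sp = []
                for endidx, v in zip((0, 1), graph.edges[e]):
                    rot = graph.rotation[v]
                    i = rot.index((e, c))
                    neigh = None
                    for off in (1, len(rot) - 1):
                        cand = end_at(v, rot[(i + off) % len(rot)])
                        if cand.capacity > 0:
                            neigh = cand
                            break
                    if neigh is None:
                        raise StapleDesignError(
                            f"no anchor for pass-through edge {e} at "
                            f"vertex {v}")
                    arm_ends.append(neigh)
                    sp.append(gap_fn(v, e, neigh.edge))
                a = min(C.ARM_DEFAULT,
                        (C.VERTEX_STAPLE_MAX - d.length_bp - sum(sp)) // 2)
                if a < C.ARM_MIN:
                    raise StapleDesignError(
                        f"pass-through staple for edge {e} cannot fit "
                        f"{C.ARM_MIN}-base arms")
                lo0, hi0 = arm_ends[0].alloc(plan, a)
                lo1, hi1 = arm_ends[1].alloc(plan, a)
                plan.arms = [(arm_ends[0], lo0, hi0), (arm_ends[1], lo1, hi1)]
                plan.spacers = sp
                plans.append(plan)

    # regular pairing, one vertex at a time
    for v in vertices:
        rot = graph.rotation[v]
        k = len(rot)
        evs = [end_at(v, inst) for inst in rot]
        made: set[frozenset] = set()

        def make(i: int, j: int) -> None:
            ea, eb = evs[i], evs[j]
            plan = _Plan()
            s = gap_fn(v, ea.edge, eb.edge)
            lo0, hi0 = ea.alloc(plan, C.ARM_DEFAULT)
            lo1, hi1 = eb.alloc(plan, C.ARM_DEFAULT)
            plan.arms = [(ea, lo0, hi0), (eb, lo1, hi1)]
            plan.spacers = [s, 0]
            plans.append(plan)
            made.add(frozenset({i, j}))

        def clamped(i: int) -> bool:
            return any(arm for arm in evs[i].arms)

        # first pass: adjacent pairs where both ends still need a clamp
        for i in range(k):
            j = (i + 1) % k
            if i == j or frozenset({i, j}) in made:
                continue
            if (evs[i].capacity > 0 and evs[j].capacity > 0
                    and not clamped(i) and not clamped(j)):
                make(i, j)
        # second pass: any still-unclamped end pairs with a neighbour that
        # has spare capacity
        for i in range(k):
            if clamped(i) or evs[i].capacity <= 0:
                continue
            for off in (1, k - 1):
                j = (i + off) % k
                if j != i and evs[j].capacity > 0 and \
                        frozenset({i, j}) not in made:
                    make(i, j)
                    break
            else:
                raise StapleDesignError(
                    f"edge {evs[i].edge} end at vertex {v} cannot be "
                    "clamped by any vertex staple")
        # third pass: extra staples where both neighbours have spare arms
        for i in range(k):
            j = (i + 1) % k
            if i == j or frozenset({i, j}) in made:
                continue
            if evs[i].capacity > 0 and evs[j].capacity > 0:
                make(i, j)

    return ends, plans


def _materialize(plan: _Plan, idx: int) -> Staple:
    steps: list[StapleStep] = []
    n = len(plan.arms)
    for i, (end, lo, hi) in enumerate(plan.arms):
        helix = (end.edge, end.role)
        steps.extend(_walk(helix, lo, hi, STAPLE_DIR[end.role]))
        if i < n - 1:
            steps.extend(_spacers(plan.spacers[i]))
    return Staple(steps=steps, cls="vertex", name=f"v{idx}")


def _materialize_passthrough(plan: _Plan, length: int, idx: int) -> Staple:
    e, role = plan.passthrough
    (ea, lo0, hi0), (eb, lo1, hi1) = plan.arms
    steps: list[StapleStep] = []
    steps.extend(_walk((ea.edge, ea.role), lo0, hi0, STAPLE_DIR[ea.role]))
    steps.extend(_spacers(plan.spacers[0]))
    steps.extend(_walk((e, role), 0, length, STAPLE_DIR[role]))
    steps.extend(_spacers(plan.spacers[1]))
    steps.extend(_walk((eb.edge, eb.role), lo1, hi1, STAPLE_DIR[eb.role]))
    return Staple(steps=steps, cls="vertex", name=f"v{idx}")


# ---------------------------------------------------------------------------
# Global designer
# ---------------------------------------------------------------------------


def design_staples(graph: EdgeGraph, designs: list[EdgeDesign],
                   bundles: dict[int, BundleLayout],
                   gap_fn=None) -> list[Staple]:
    """Design every staple of a structure.

    Plans vertex staples (fixing the arm reserves), covers each edge's
    helices with bundle or plain modular staples, merges sub-minimal
    remainders into the adjacent vertex arms, and materializes
    everything.  The result satisfies the global occupancy contract:
    every staple-side base of every helix is covered exactly once.
    """
    by_edge = {d.edge: d for d in designs}
    ends, plans = _plan_vertex_staples(graph, designs, gap_fn)
    passthrough = {p.passthrough for p in plans if p.passthrough is not None}

    staples: list[Staple] = []
    for e, d in sorted(by_edge.items()):
        reserves = {}
        for c in range(graph.multiplicity[e]):
            role = "main" if c == 0 else "main2"
            if (e, role) in passthrough:
                # fully spanned by its pass-through vertex staple
                reserves[(role, 0)] = d.length_bp
                reserves[(role, 1)] = 0
                continue
            for endidx in (0, 1):
                reserves[(role, endidx)] = ends[(e, c, endidx)].allocated
        if e in bundles:
            st, extensions = design_bundle_staples(bundles[e], reserves)
        else:
            st, extensions = design_edge_staples(d, reserves)
        staples.extend(st)
        _apply_extensions(ends, e, extensions)

    for i, plan in enumerate(plans):
        if plan.passthrough is not None:
            e, role = plan.passthrough
            staples.append(_materialize_passthrough(
                plan, by_edge[e].length_bp, i))
        else:
            staples.append(_materialize(plan, i))

    _check_vertex_lengths(staples)
    return staples


def _apply_extensions(ends, edge, extensions) -> None:
    """Grow innermost vertex arms over sub-14-base helix remainders."""
    for (role, endidx), extra in extensions.items():
        copy = 0 if role == "main" else 1
        choices = [ends[(edge, copy, endidx)], ends[(edge, copy, 1 - endidx)]]
        remaining = extra
        for end in choices:
            if remaining == 0:
                break
            if not end.arms:
                continue
            arm = end.arms[-1]  # innermost allocation
            plan = arm[0]
            cur_len = sum(hi - lo for _, lo, hi in plan.arms) + \
                sum(plan.spacers)
            if plan.passthrough is not None:
                cur_len += 0  # middle added at materialization; be strict
            room = C.VERTEX_STAPLE_MAX - cur_len
            if plan.passthrough is not None:
                room = 0
            take = min(remaining, max(0, room))
            take = min(take, C.ARM_MAX - (arm[2] - arm[1]))
            if take <= 0:
                continue
            if end.end == 0:
                arm[2] += take
                new = (end, arm[1], arm[2])
            else:
                arm[1] -= take
                new = (end, arm[1], arm[2])
            for i, (pe, lo, hi) in enumerate(plan.arms):
                if pe is end:
                    plan.arms[i] = new
                    break
            remaining -= take
        if remaining:
            raise StapleDesignError(
                f"cannot absorb {remaining}-base remainder on edge {edge} "
                f"{role} end {endidx}")


def _check_vertex_lengths(staples: list[Staple]) -> None:
    for st in staples:
        if st.cls == "vertex" and not (
                C.VERTEX_STAPLE_MIN <= st.length <= C.VERTEX_STAPLE_MAX):
            raise StapleDesignError(
                f"vertex staple {st.name} length {st.length} outside "
                f"[{C.VERTEX_STAPLE_MIN}, {C.VERTEX_STAPLE_MAX}]")
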