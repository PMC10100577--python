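"""Four-helix-bundle reinforcement of wireframe edges.

A reinforced edge carries four parallel helices on a 2x2 square-lattice
footprint: the main scaffold helix, two slightly shorter scaffold *loop*
helices extruded from the main helix at a double crossover and closed by
end-loops, and a fourth helix made of *mini-scaffolds* — short synthetic
strands (30-60 nt) that play the scaffold's role without being connected
to it.  Edges that were doubled during Eulerianization already carry two
scaffold helices, so only the loop pair is added and no mini helix.

Generation criteria:

* loops are added only to edges selected for reinforcement, and only if
  the edge has more than ``threshold`` (default 30) bases, so that a
  stable loop can be extruded;
* loop helices span between the outermost admissible end-loop positions
  at least 5 bases inside the main helix ends;
* the mini helix has the same length as the main helix and is split into
  oligos of 30-60 bases for standard synthesis.

Crossover admissibility follows the square-lattice convention: positions
repeat mod 8 with a per-neighbour-direction offset (scaffold double
crossovers at 3 mod 8, end-loops and staple crossovers at 0/7 mod 8),
with a 32-base super-period matching staple modularity.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import constants as C
from .errors import GeometryError, InfeasibleError, NotReinforceableError
from .layout import EdgeDesign

__all__ = [
    "ReinforceParams", "BundleLayout",
    "loop_span", "place_crossovers", "split_miniscaffold", "reinforce_edge",
    "select_reinforced",
]


@dataclass(frozen=True)
class ReinforceParams:
    threshold: int = C.REINFORCE_THRESHOLD
    end_margin: int = C.LOOP_END_MARGIN
    extra_xover_every: int = 96  # three super-periods


#: Lattice footprint of a reinforced single edge (row, col) and the
#: cyclic helix ring used by the staple weave.
SINGLE_RING = ("main", "loopA", "loopB", "mini")
DOUBLE_RING = ("main", "loopA", "loopB", "main2")
FOOTPRINT = {"main": (0, 0), "loopA": (1, 0), "loopB": (1, 1),
             "mini": (0, 1), "main2": (0, 1)}


@dataclass(frozen=True)
class BundleLayout:
    """Placement of the helices, crossovers and mini oligos of one edge.

    ``loop_lo``/``loop_hi`` are the inclusive base indices of the loop
    helix span on the main helix's coordinate axis.  ``xover_sites``
    lists admissible double-crossover positions c (each site pairs bases
    c and c+1 on main <-> loopA); the first entry is the scaffold's
    excursion site, any further sites are realized in the staple layer.
    """
    edge: int
    length_bp: int
    is_double: bool
    ring: tuple[str, ...]
    loop_lo: int
    loop_hi: int
    xover_sites: tuple[int, ...]
    mini_oligos: tuple[int, ...]  # empty for double edges

    @property
    def scaffold_site(self) -> int:
        return self.xover_sites[0]

    @property
    def loop_length(self) -> int:
        return self.loop_hi - self.loop_lo + 1

    def footprint(self) -> dict[str, tuple[int, int]]:
        return {role: FOOTPRINT[role] for role in self.ring}


def loop_span(length_bp: int,
              end_margin: int = C.LOOP_END_MARGIN) -> tuple[int, int]:
    """Inclusive span of the loop helices: the outermost admissible
    end-loop positions (7 mod 8) at least ``end_margin`` bases inside the
    main helix ends."""
    lo = end_margin + (-(end_margin - C.ENDLOOP_OFFSET)) % C.XOVER_PERIOD
    hi_limit = length_bp - 1 - end_margin
    hi = hi_limit - (hi_limit - C.ENDLOOP_OFFSET) % C.XOVER_PERIOD
    if hi <= lo:
        raise GeometryError(
            f"no admissible end-loop span for a {length_bp} bp edge")
    return lo, hi


def place_crossovers(length_bp: int,
                     params: ReinforceParams = ReinforceParams(),
                     ) -> tuple[tuple[int, ...], tuple[int, int]]:
    """Double-crossover sites and the end-loop span for one edge.

    One site is placed at the admissible position (3 mod 8) nearest the
    edge midpoint; edges longer than ``threshold`` gain one site per
    further 96 bases, spread evenly.  Returns (sites, (loop_lo, loop_hi)).
    """
    if length_bp <= params.threshold:
        raise GeometryError(
            f"{length_bp} bp edge is at or below threshold; no crossovers")
    lo, hi = loop_span(length_bp, params.end_margin)
    # admissible: c in [lo+1, hi-2] with c % 8 == SCAFFOLD_XOVER_OFFSET
    first = lo + 1 + (-(lo + 1 - C.SCAFFOLD_XOVER_OFFSET)) % C.XOVER_PERIOD
    admissible = list(range(first, hi - 1, C.XOVER_PERIOD))
    if not admissible:
        raise GeometryError(
            f"no admissible double-crossover position on a {length_bp} bp "
            f"edge (span {lo}..{hi})")
    n = max(1, (length_bp - params.threshold) // params.extra_xover_every)
    n = min(n, len(admissible))
    mid = (length_bp - 1) / 2
    sites = [min(admissible, key=lambda c: (abs(c - mid), c))]
    if n > 1:
        # spread the extra sites over the admissible range, keeping the
        # mid-edge site; choose nearest admissible to even quantiles
        targets = [lo + (k + 1) * (hi - lo) / (n + 1) for k in range(n)]
        for t in targets:
            cand = min(admissible, key=lambda c: (abs(c - t), c))
            if cand not in sites:
                sites.append(cand)
            if len(sites) == n:
                break
        for cand in admissible:  # fill up deterministically if quantiles tied
            if len(sites) == n:
                break
            if cand not in sites:
                sites.append(cand)
    first_site = sites[0]
    rest = sorted(sites[1:])
    return tuple([first_site] + rest), (lo, hi)


def split_miniscaffold(length_bp: int) -> tuple[int, ...]:
    """Split a mini helix into synthesizable oligo lengths.

    ``ceil(length/60)`` pieces, as even as possible, each within the
    30-60 base synthesis window.  Below 30 bases no split can satisfy the
    floor and an :class:`InfeasibleError` is raised.
    """
    if length_bp < C.MINI_OLIGO_MIN:
        raise InfeasibleError(
            f"mini helix of {length_bp} bp cannot be split into "
            f">= {C.MINI_OLIGO_MIN} base oligos")
    n = -(-length_bp // C.MINI_OLIGO_MAX)
    base, rem = divmod(length_bp, n)
    pieces = tuple([base + 1] * rem + [base] * (n - rem))
    assert all(C.MINI_OLIGO_MIN <= p <= C.MINI_OLIGO_MAX for p in pieces)
    return pieces


def reinforce_edge(design: EdgeDesign,
                   params: ReinforceParams = ReinforceParams(),
                   ) -> BundleLayout:
    """Compute the 2x2 bundle layout for one edge marked for
    reinforcement.

    Raises :class:`NotReinforceableError` at or below the threshold and
    :class:`GeometryError` when the edge cannot host one admissible
    double crossover inside the end margins.
    """
    if design.length_bp <= params.threshold:
        raise NotReinforceableError(
            f"edge {design.edge} has {design.length_bp} bp; reinforcement "
            f"needs more than {params.threshold}")
    sites, (lo, hi) = place_crossovers(design.length_bp, params)
    if design.is_double:
        ring = DOUBLE_RING
        minis: tuple[int, ...] = ()
    else:
        ring = SINGLE_RING
        minis = split_miniscaffold(design.length_bp)
    return BundleLayout(
        edge=design.edge,
        length_bp=design.length_bp,
        is_double=design.is_double,
        ring=ring,
        loop_lo=lo,
        loop_hi=hi,
        xover_sites=sites,
        mini_oligos=minis,
    )


def select_reinforced(designs: list[EdgeDesign], requested: set[int] | None,
                      params: ReinforceParams = ReinforceParams(),
                      ) -> tuple[list[EdgeDesign], list[int]]:
    """Apply the reinforcement criteria to a user selection.

    ``requested`` is the set of edge ids the user asked to reinforce
    (``None`` = all).  Edges at or below the threshold are silently left
    unreinforced and reported in the returned skip list, matching the
    automatic generation criteria.
    """
    out = []
    skipped = []
    for d in designs:
        want = requested is None or d.edge in requested
        if want and d.length_bp > params.threshold:
            out.append(EdgeDesign(edge=d.edge, length_bp=d.length_bp,
                                  length_nm=d.length_nm, reinforced=True,
                                  is_double=d.is_double))
        else:
            if want:
                skipped.append(d.edge)
            out.append(d)
    return out, skipped
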