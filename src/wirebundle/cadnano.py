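"""Global strand model assembly, sequence threading and caDNAno JSON I/O.

The strand model places every helix of the design on a square lattice
(each edge owns a distinct 2x2 block of (row, col) slots), splices the
loop excursions of reinforced edges into the A-trail to form the single
closed scaffold circuit, lays the mini-scaffold oligos on their own
helix (never connected to the scaffold), and checks the global occupancy
contract: every base of every helix span is claimed exactly once on the
scaffold side and exactly once on the staple side.

The caDNAno document uses the square-lattice JSON flavour: per-helix
``scaf``/``stap`` pointer arrays whose 4-tuples must be mutually
reciprocal, with ``loop``/``skip`` arrays present but zero-filled.
Serialization is byte-stable (sorted keys, fixed separators) so that
write -> read -> write round-trips identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import AssemblyError, BudgetError, CadnanoFormatError
from .layout import EdgeDesign
from .mesh import EdgeGraph
from .reinforce import FOOTPRINT, BundleLayout
from .routing import ATrail
from .staples import Staple

__all__ = [
    "Helix", "StrandModel", "CadnanoDoc", "SequenceTable",
    "build_strand_model", "write_cadnano", "read_cadnano",
    "thread_sequences", "random_scaffold",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

STAPLE_COLORS = {"vertex": 0x0066CC, "bundle": 0xB8056C,
                 "bundle_interior": 0xCC0000, "mini": 0x888888}


@dataclass(frozen=True)
class Helix:
    num: int
    row: int
    col: int
    edge: int
    role: str
    length: int
    span: tuple[int, int]  # [lo, hi) occupied base range


@dataclass(frozen=True)
class PathStep:
    helix: int   # -1 for an unpaired spacer base
    base: int
    paired: bool


@dataclass
class StrandModel:
    helices: list[Helix]
    helix_of: dict[tuple[int, str], int]   # (edge, role) -> helix num
    scaffold: list[PathStep]               # single closed circuit
    minis: list[list[PathStep]]            # disjoint from the scaffold
    staples: list[Staple]

    def helix(self, num: int) -> Helix:
        return self.helices[num]

    def scaffold_bases_used(self) -> int:
        return len(self.scaffold)

    def occupancy(self) -> tuple[dict, dict]:
        """(scaffold-side, staple-side) maps of (helix, base) -> strand
        label; raises :class:`AssemblyError` on any double claim."""
        scaf: dict[tuple[int, int], str] = {}
        stap: dict[tuple[int, int], str] = {}

        def claim(side: dict, h: int, b: int, label: str) -> None:
            if (h, b) in side:
                raise AssemblyError(
                    f"base ({h},{b}) claimed by {side[(h, b)]} and {label}")
            side[(h, b)] = label

        for s in self.scaffold:
            if s.helix >= 0:
                claim(scaf, s.helix, s.base, "scaffold")
        for i, oligo in enumerate(self.minis):
            for s in oligo:
                claim(scaf, s.helix, s.base, f"mini{i}")
        for st in self.staples:
            for s in st.steps:
                if s.helix is None:
                    continue
                h = self.helix_of[s.helix]
                claim(stap, h, s.base, st.name or "staple")
        return scaf, stap

    def validate_occupancy(self) -> None:
        scaf, stap = self.occupancy()
        want = {(h.num, b) for h in self.helices
                for b in range(h.span[0], h.span[1])}
        for side, got in (("scaffold", set(scaf)), ("staple", set(stap))):
            missing = want - got
            extra = got - want
            if missing or extra:
                raise AssemblyError(
                    f"{side}-side coverage mismatch: missing {sorted(missing)[:5]}"
                    f" extra {sorted(extra)[:5]}")


def _helix_layout(graph: EdgeGraph, designs: list[EdgeDesign],
                  bundles: dict[int, BundleLayout]) -> tuple[list[Helix],
                                                             dict]:
    helices: list[Helix] = []
    helix_of: dict[tuple[int, str], int] = {}
    by_edge = {d.edge: d for d in designs}
    for e in sorted(by_edge):
        d = by_edge[e]
        L = d.length_bp
        if e in bundles:
            b = bundles[e]
            roles = list(b.ring)
            spans = {}
            for r in roles:
                if r in ("loopA", "loopB"):
                    spans[r] = (b.loop_lo, b.loop_hi + 1)
                else:
                    spans[r] = (0, L)
        else:
            roles = ["main", "main2"] if d.is_double else ["main"]
            spans = {r: (0, L) for r in roles}
        for r in roles:
            row, col = FOOTPRINT[r]
            num = len(helices)
            helices.append(Helix(num=num, row=row, col=2 * e + col,
                                 edge=e, role=r, length=L, span=spans[r]))
            helix_of[(e, r)] = num
    return helices, helix_of


def _excursion(b: BundleLayout, hA: int, hB: int,
               direction: int) -> list[PathStep]:
    """Loop excursion steps for a traversal of the main helix in
    ``direction``; entered at the scaffold double-crossover site."""
    c = b.scaffold_site
    lo, hi = b.loop_lo, b.loop_hi
    steps: list[PathStep] = []
    if direction > 0:
        steps += [PathStep(hA, x, True) for x in range(c, lo - 1, -1)]
        steps += [PathStep(hB, x, True) for x in range(lo, hi + 1)]
        steps += [PathStep(hA, x, True) for x in range(hi, c, -1)]
    else:
        steps += [PathStep(hA, x, True) for x in range(c + 1, hi + 1)]
        steps += [PathStep(hB, x, True) for x in range(hi, lo - 1, -1)]
        steps += [PathStep(hA, x, True) for x in range(lo, c + 1)]
    return steps


def build_strand_model(graph: EdgeGraph, trail: ATrail,
                       designs: list[EdgeDesign],
                       bundles: dict[int, BundleLayout],
                       staples: list[Staple],
                       spacer_counts: list[int] | None = None) -> StrandModel:
    """Assemble and validate the global strand model.

    The scaffold circuit follows the A-trail main helices, detours
    through each reinforced edge's loop pair at its double-crossover
    site, and carries the vertex spacer bases between edges.
    """
    by_edge = {d.edge: d for d in designs}
    for e in bundles:
        if e not in by_edge:
            raise AssemblyError(f"bundle references unknown edge {e}")
    helices, helix_of = _helix_layout(graph, designs, bundles)
    if spacer_counts is None:
        spacer_counts = [2] * len(trail.steps)

    scaffold: list[PathStep] = []
    for i, s in enumerate(trail.steps):
        if s.edge not in by_edge:
            raise AssemblyError(f"trail step references unknown edge {s.edge}")
        d = by_edge[s.edge]
        L = d.length_bp
        u, v = graph.edges[s.edge]
        direction = +1 if s.tail == u else -1
        role = "main" if s.copy == 0 else "main2"
        h = helix_of[(s.edge, role)]
        bases = range(0, L) if direction > 0 else range(L - 1, -1, -1)
        bundle = bundles.get(s.edge)
        do_excursion = bundle is not None and s.copy == 0
        for b in bases:
            scaffold.append(PathStep(h, b, True))
            if do_excursion:
                c = bundle.scaffold_site
                hit = (direction > 0 and b == c) or \
                      (direction < 0 and b == c + 1)
                if hit:
                    scaffold.extend(_excursion(
                        bundle, helix_of[(s.edge, "loopA")],
                        helix_of[(s.edge, "loopB")], direction))
        for _ in range(spacer_counts[i]):
            scaffold.append(PathStep(-1, -1, False))

    minis: list[list[PathStep]] = []
    for e in sorted(bundles):
        b = bundles[e]
        if b.is_double:
            continue
        h = helix_of[(e, "mini")]
        L = b.length_bp
        # canonical mini scaffold-side direction is -, so oligos walk
        # from base L-1 downwards
        at = L - 1
        for length in b.mini_oligos:
            minis.append([PathStep(h, at - k, True) for k in range(length)])
            at -= length

    model = StrandModel(helices=helices, helix_of=helix_of,
                        scaffold=scaffold, minis=minis, staples=staples)
    model.validate_occupancy()
    return model


# ---------------------------------------------------------------------------
# caDNAno JSON
# ---------------------------------------------------------------------------


@dataclass
class CadnanoDoc:
    name: str
    vstrands: list[dict] = field(default_factory=list)

    def to_obj(self) -> dict:
        return {"name": self.name, "vstrands": self.vstrands}

    def pointer_graph(self) -> dict:
        """Canonical {(strand, helix, base): 4-tuple} map for equality
        checks independent of array padding."""
        out = {}
        for vs in self.vstrands:
            for strand in ("scaf", "stap"):
                for b, cell in enumerate(vs[strand]):
                    if cell != [-1, -1, -1, -1]:
                        out[(strand, vs["num"], b)] = tuple(cell)
        return out


def _empty_cells(n: int) -> list[list[int]]:
    return [[-1, -1, -1, -1] for _ in range(n)]


def _link(cells: dict, chain: list[tuple[int, int]], circular: bool) -> None:
    n = len(chain)
    for i, (h, b) in enumerate(chain):
        cell = cells[(h, b)]
        if i > 0 or circular:
            ph, pb = chain[(i - 1) % n]
            cell[0], cell[1] = ph, pb
        if i < n - 1 or circular:
            nh, nb = chain[(i + 1) % n]
            cell[2], cell[3] = nh, nb


def model_to_cadnano(model: StrandModel, name: str = "wirebundle") -> CadnanoDoc:
    maxlen = max((h.length for h in model.helices), default=0)
    arrlen = -(-max(maxlen, 1) // 32) * 32

    scaf_cells = {}
    stap_cells = {}
    vstrands = []
    for h in model.helices:
        vs = {
            "num": h.num, "row": h.row, "col": h.col,
            "scaf": _empty_cells(arrlen), "stap": _empty_cells(arrlen),
            "loop": [0] * arrlen, "skip": [0] * arrlen,
            "stap_colors": [],
        }
        vstrands.append(vs)
        for b in range(arrlen):
            scaf_cells[(h.num, b)] = vs["scaf"][b]
            stap_cells[(h.num, b)] = vs["stap"][b]

    chain = [(s.helix, s.base) for s in model.scaffold if s.helix >= 0]
    if chain:
        _link(scaf_cells, chain, circular=True)
    for oligo in model.minis:
        _link(scaf_cells, [(s.helix, s.base) for s in oligo], circular=False)

    for st in model.staples:
        chain = [(model.helix_of[s.helix], s.base) for s in st.steps
                 if s.helix is not None]
        _link(stap_cells, chain, circular=False)
        h5, b5 = chain[0]
        color = STAPLE_COLORS["bundle_interior"] if st.interior else \
            STAPLE_COLORS[st.cls]
        vstrands[h5]["stap_colors"].append([b5, color])
    for vs in vstrands:
        vs["stap_colors"].sort()
    return CadnanoDoc(name=name, vstrands=vstrands)


def write_cadnano(model_or_doc, path: str | Path,
                  name: str = "wirebundle") -> CadnanoDoc:
    """Serialize to caDNAno JSON with byte-stable field ordering."""
    doc = model_or_doc if isinstance(model_or_doc, CadnanoDoc) else \
        model_to_cadnano(model_or_doc, name=name)
    text = json.dumps(doc.to_obj(), sort_keys=True, separators=(",", ":"))
    Path(path).write_text(text)
    return doc


def read_cadnano(path: str | Path) -> CadnanoDoc:
    """Read and validate a caDNAno JSON document.

    Checks that every non-empty pointer is reciprocated and that lattice
    coordinates are unique; failures name the offending cell.
    """
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise CadnanoFormatError(f"{path}: malformed JSON: {exc}") from exc
    if "vstrands" not in obj:
        raise CadnanoFormatError(f"{path}: missing 'vstrands'")
    doc = CadnanoDoc(name=obj.get("name", ""), vstrands=obj["vstrands"])

    by_num = {}
    coords = {}
    for vs in doc.vstrands:
        if vs["num"] in by_num:
            raise CadnanoFormatError(f"duplicate helix num {vs['num']}")
        by_num[vs["num"]] = vs
        rc = (vs["row"], vs["col"])
        if rc in coords:
            raise CadnanoFormatError(
                f"helices {coords[rc]} and {vs['num']} share lattice "
                f"coordinates {rc}")
        coords[rc] = vs["num"]

    for vs in doc.vstrands:
        for strand in ("scaf", "stap"):
            arr = vs[strand]
            for b, cell in enumerate(arr):
                ph, pb, nh, nb = cell
                if nh >= 0:
                    target = by_num.get(nh)
                    if target is None or not (0 <= nb < len(target[strand])):
                        raise CadnanoFormatError(
                            f"{strand}[{vs['num']}][{b}] points to missing "
                            f"cell ({nh},{nb})")
                    back = target[strand][nb]
                    if (back[0], back[1]) != (vs["num"], b):
                        raise CadnanoFormatError(
                            f"non-reciprocal pointer at {strand} cell "
                            f"({vs['num']},{b}) -> ({nh},{nb})")
                if ph >= 0:
                    target = by_num.get(ph)
                    if target is None or not (0 <= pb < len(target[strand])):
                        raise CadnanoFormatError(
                            f"{strand}[{vs['num']}][{b}] points to missing "
                            f"cell ({ph},{pb})")
                    back = target[strand][pb]
                    if (back[2], back[3]) != (vs["num"], b):
                        raise CadnanoFormatError(
                            f"non-reciprocal pointer at {strand} cell "
                            f"({vs['num']},{b}) -> ({ph},{pb})")
    return doc


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def random_scaffold(n: int, seed: int) -> str:
    """Seeded pseudorandom sequence with 50% GC and no homopolymer run
    longer than 4 (stand-in for an external scaffold like p7560)."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    out: list[str] = []
    while len(out) < n:
        c = bases[rng.integers(4)]
        if len(out) >= 4 and all(x == c for x in out[-4:]):
            continue
        out.append(c)
    return "".join(out)


@dataclass
class SequenceTable:
    """Named sequences of every staple and mini oligo plus the scaffold
    actually threaded."""
    scaffold: str
    rows: list[dict]

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.rows,
                            columns=["name", "class", "well", "length",
                                     "sequence"])

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def thread_sequences(model: StrandModel, scaffold: str | None = None,
                     seed: int = 0) -> SequenceTable:
    """Assign sequences along the scaffold circuit and derive staple and
    mini-oligo sequences by Watson-Crick complementarity.

    The scaffold is threaded from the declared start (the first circuit
    step); unpaired scaffold bases at vertices consume scaffold sequence
    too.  Staple bases are the complement of whatever scaffold-side
    strand (scaffold or mini) occupies their position; designed spacer
    bases are T.
    """
    need = len(model.scaffold)
    if scaffold is None:
        scaffold = random_scaffold(need, seed)
    scaffold = scaffold.upper()
    if len(scaffold) < need:
        raise BudgetError(
            f"scaffold of {len(scaffold)} bases cannot thread a circuit of "
            f"{need} bases (see check_scaffold_budget)")

    scaf_base: dict[tuple[int, int], str] = {}
    for i, s in enumerate(model.scaffold):
        if s.helix >= 0:
            scaf_base[(s.helix, s.base)] = scaffold[i]

    rows = []
    rng = np.random.default_rng(seed + 1)
    for i, oligo in enumerate(model.minis):
        seq = random_scaffold(len(oligo), int(rng.integers(2 ** 31)))
        for s, c in zip(oligo, seq):
            scaf_base[(s.helix, s.base)] = c
        rows.append({"name": f"mini_{i:03d}", "class": "mini", "well": "",
                     "length": len(oligo), "sequence": seq})

    for i, st in enumerate(model.staples):
        chars = []
        for s in st.steps:
            if s.helix is None:
                chars.append("T")
            else:
                h = model.helix_of[s.helix]
                partner = scaf_base.get((h, s.base))
                if partner is None:
                    raise AssemblyError(
                        f"staple {st.name} pairs unoccupied base "
                        f"({h},{s.base})")
                chars.append(partner.translate(_COMPLEMENT))
        rows.append({"name": st.name or f"staple_{i:03d}",
                     "class": st.cls, "well": "",
                     "length": st.length, "sequence": "".join(chars)})
    return SequenceTable(scaffold=scaffold[:need], rows=rows)
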