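"""Staple classes: modular bundle staples, vertex staples, T spacers."""

import numpy as np
import pytest

from helpers import staple_side_occupancy
from wirebundle.layout import EdgeDesign, assign_edge_lengths
from wirebundle.mesh import build_edge_graph, generate_fixture_mesh
from wirebundle.pipeline import PipelineConfig, run_pipeline
from wirebundle.reinforce import reinforce_edge
from wirebundle.staples import (compute_t_spacers, design_bundle_staples,
                                design_staples, design_vertex_staples)


def bundle_of(length, double=False):
    d = EdgeDesign(edge=0, length_bp=length, length_nm=round(length * .34, 1),
                   reinforced=True, is_double=double)
    return reinforce_edge(d)


def coverage_by_helix(staples):
    cov = {}
    for st in staples:
        for s in st.steps:
            if s.helix is None:
                continue
            cov.setdefault(s.helix, []).append(s.base)
    return cov


class TestBundleStaples:
    @pytest.mark.parametrize("length", [96, 100, 128, 160, 230])
    def test_interior_staples_are_32_with_single_16_seed(self, length):
        staples, _ = design_bundle_staples(
            bundle_of(length), {("main", 0): 16, ("main", 1): 16})
        interior = [s for s in staples if s.interior]
        assert interior, "expected at least one interior module"
        for st in interior:
            assert st.length == 32
            assert st.seed_length == 16
            doms = [hi - lo + 1 for _, lo, hi in st.domains()]
            assert sorted(doms) == [8, 8, 16]

    def test_full_coverage_each_base_once(self):
        b = bundle_of(100)
        reserves = {("main", 0): 32, ("main", 1): 32}
        staples, ext = design_bundle_staples(b, reserves)
        assert not ext
        cov = coverage_by_helix(staples)
        # main: everything between the arm reserves
        assert sorted(cov[(0, "main")]) == list(range(32, 68))
        # loops: the whole span, exactly once
        span = list(range(b.loop_lo, b.loop_hi + 1))
        assert sorted(cov[(0, "loopA")]) == span
        assert sorted(cov[(0, "loopB")]) == span
        # mini: the full edge length
        assert sorted(cov[(0, "mini")]) == list(range(100))

    def test_short_bundle_terminal_only(self):
        staples, _ = design_bundle_staples(
            bundle_of(40), {("main", 0): 16, ("main", 1): 16})
        assert all(not s.interior for s in staples)
        assert all(14 <= s.length <= 60 for s in staples)

    def test_double_edge_bundle_covers_both_mains(self):
        b = bundle_of(100, double=True)
        reserves = {("main", 0): 32, ("main", 1): 32,
                    ("main2", 0): 32, ("main2", 1): 32}
        staples, _ = design_bundle_staples(b, reserves)
        cov = coverage_by_helix(staples)
        assert sorted(cov[(0, "main2")]) == list(range(32, 68))
        assert (0, "mini") not in cov

    def test_nicks_avoid_scaffold_crossovers(self):
        for L in (31, 40, 50, 64, 96, 100, 150, 230):
            b = bundle_of(L)
            r = 16 if L >= 37 else 0
            staples, _ = design_bundle_staples(
                b, {("main", 0): r, ("main", 1): r})
            c = b.scaffold_site
            forbidden = {
                "main": {c, c + 1},
                "loopA": {c, c + 1, b.loop_lo, b.loop_hi},
                "loopB": {b.loop_lo, b.loop_hi},
            }
            for st in staples:
                for s in (st.steps[0], st.steps[-1]):
                    bad = forbidden.get(s.helix[1], set())
                    assert s.base not in bad, (L, st.name, s)


class TestVertexStaples:
    def test_octahedron_vertex_gets_four_staples(self, octahedron_graph):
        """Degree-4 vertex with long edges: one staple per rotation-
        adjacent edge pair."""
        designs = [EdgeDesign(e, 100, 34.0)
                   for e in range(len(octahedron_graph.edges))]
        staples = design_vertex_staples(octahedron_graph, 0, designs)
        at_vertex = [s for s in staples]
        assert len(at_vertex) == 4
        for st in at_vertex:
            assert st.cls == "vertex"
            assert 30 <= st.length <= 60

    def test_unpaired_bases_only_in_vertex_staples(self, pentagon_mesh):
        res = run_pipeline(pentagon_mesh, PipelineConfig(scale=1.0, seed=0))
        for st in res.staples:
            unpaired = [s for s in st.steps if not s.paired]
            if unpaired:
                assert st.cls == "vertex"
                assert all(s.helix is None for s in unpaired)

    def test_all_staple_length_bounds(self, pentagon_mesh):
        res = run_pipeline(pentagon_mesh, PipelineConfig(scale=1.0, seed=0))
        for st in res.staples:
            assert 14 <= st.length <= 60
            if st.cls == "vertex":
                assert 30 <= st.length <= 60

    def test_every_edge_end_clamped(self, pentagon_mesh):
        """Each scaffold-helix end must carry at least one vertex staple
        arm within its outermost 32 bases."""
        res = run_pipeline(pentagon_mesh, PipelineConfig(scale=1.0, seed=0))
        ends = {}
        for st in res.staples:
            if st.cls != "vertex":
                continue
            for helix, lo, hi in st.domains():
                L = next(d.length_bp for d in res.designs
                         if d.edge == helix[0])
                if lo < 32:
                    ends[(helix, 0)] = True
                if hi >= L - 32:
                    ends[(helix, 1)] = True
        for d in res.designs:
            for c in range(2 if d.is_double else 1):
                role = "main" if c == 0 else "main2"
                assert ends.get(((d.edge, role), 0)), (d.edge, role)
                assert ends.get(((d.edge, role), 1)), (d.edge, role)

    def test_doubled_pair_spanned_by_staple(self, pentagon_mesh):
        """The two copies of a doubled edge are rotation-adjacent, so a
        vertex staple must span main and main2 of the same edge."""
        res = run_pipeline(pentagon_mesh, PipelineConfig(scale=1.0, seed=0))
        doubled = set(res.doubled)
        assert doubled
        found = False
        for st in res.staples:
            if st.cls != "vertex":
                continue
            helices = {h for h, _, _ in st.domains()}
            for e in doubled:
                if {(e, "main"), (e, "main2")} <= helices:
                    found = True
        assert found

    def test_short_edge_passthrough(self):
        """A 24 bp edge cannot host its own arms; one staple must span
        it with arms on the neighbouring edges."""
        mesh = generate_fixture_mesh("triangle", scale=34.0)
        graph = build_edge_graph(mesh)
        designs = assign_edge_lengths(mesh, 1.0, graph)  # 100 bp sides
        from dataclasses import replace
        designs[1] = replace(designs[1], length_bp=24, length_nm=8.2)
        staples = design_staples(graph, designs, {})
        spanning = [st for st in staples
                    if any(h == (1, "main") for h, _, _ in st.domains())]
        assert len(spanning) == 1
        st = spanning[0]
        assert st.cls == "vertex" and 30 <= st.length <= 60
        helices = {h for h, _, _ in st.domains()}
        assert helices == {(0, "main"), (1, "main"), (2, "main")}
        # the short edge is covered end to end by that one staple
        mid = [(lo, hi) for h, lo, hi in st.domains() if h == (1, "main")]
        assert mid == [(0, 23)]


class TestTSpacers:
    @pytest.mark.parametrize("gap,count", [
        (0.0, 0), (0.8, 2), (10.0, 5), (0.39, 1), (2.0, 5),
    ])
    def test_formula_and_clamp(self, gap, count):
        assert compute_t_spacers(gap) == count

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            compute_t_spacers(-0.1)


class TestGlobalOccupancy:
    @pytest.mark.parametrize("name,kw,bp", [
        ("triangle", {}, 100),
        ("fan_polygon", {"n": 5}, 100),
        ("octahedron", {}, 120),
        ("square_rod", {"segments": 2}, 50),
    ])
    def test_staple_side_covered_exactly_once(self, name, kw, bp):
        mesh = generate_fixture_mesh(name, **kw)
        graph = build_edge_graph(mesh)
        lengths = [np.linalg.norm(mesh.vertices[b] - mesh.vertices[a])
                   for a, b in graph.edges]
        scale = bp * 0.34 / min(lengths)
        res = run_pipeline(mesh, PipelineConfig(scale=scale, seed=0))
        counts = staple_side_occupancy(res.model)
        assert all(c == 1 for c in counts.values())
        want = {(h.num, b) for h in res.model.helices
                for b in range(h.span[0], h.span[1])}
        assert set(counts) == want
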