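"""Strand model assembly, sequence threading and caDNAno round-trips."""

import json

import numpy as np
import pytest

from helpers import scaffold_side_occupancy
from wirebundle.cadnano import (StrandModel, model_to_cadnano,
                                random_scaffold, read_cadnano,
                                thread_sequences, write_cadnano)
from wirebundle.errors import BudgetError, CadnanoFormatError
from wirebundle.mesh import build_edge_graph, generate_fixture_mesh
from wirebundle.pipeline import PipelineConfig, run_pipeline

COMPL = {"A": "T", "T": "A", "C": "G", "G": "C"}


@pytest.fixture(scope="module")
def pentagon_result():
    rim = 2 * np.sin(np.pi / 5)
    mesh = generate_fixture_mesh("fan_polygon", n=5, scale=34.0 / rim)
    return run_pipeline(mesh, PipelineConfig(scale=1.0, seed=1))


@pytest.fixture(scope="module")
def triangle_result():
    mesh = generate_fixture_mesh("triangle", scale=34.0)
    return run_pipeline(mesh, PipelineConfig(scale=1.0, reinforce="none",
                                             seed=0))


class TestStrandModel:
    def test_scaffold_is_single_closed_circuit(self, pentagon_result):
        model = pentagon_result.model
        # every paired step's helix/base is unique and the walk is closed
        seen = set()
        for s in model.scaffold:
            if s.helix >= 0:
                assert (s.helix, s.base) not in seen
                seen.add((s.helix, s.base))

    def test_scaffold_conservation(self, pentagon_result):
        """Circuit length = main helices (doubled edges twice) + loop
        helices of reinforced edges + vertex spacers, and equals the
        budget report's count."""
        res = pentagon_result
        mains = sum(next(d.length_bp for d in res.designs if d.edge == s.edge)
                    for s in res.trail.steps)
        loops = sum(2 * b.loop_length for b in res.bundles.values())
        spacers = sum(1 for s in res.model.scaffold if s.helix < 0)
        assert len(res.model.scaffold) == mains + loops + spacers
        assert res.budget.used == len(res.model.scaffold)

    def test_minis_disjoint_from_scaffold(self, pentagon_result):
        model = pentagon_result.model
        scaffold_bases = {(s.helix, s.base) for s in model.scaffold
                         if s.helix >= 0}
        mini_bases = {(s.helix, s.base) for o in model.minis for s in o}
        assert not (scaffold_bases & mini_bases)
        assert all(c == 1 for c in scaffold_side_occupancy(model).values())

    def test_mini_sum_equals_edge_lengths(self, pentagon_result):
        res = pentagon_result
        by_helix = {}
        for o in res.model.minis:
            h = o[0].helix
            by_helix[h] = by_helix.get(h, 0) + len(o)
        for e, b in res.bundles.items():
            if b.is_double:
                continue
            h = res.model.helix_of[(e, "mini")]
            assert by_helix[h] == b.length_bp

    def test_lattice_coordinates_unique(self, pentagon_result):
        coords = [(h.row, h.col) for h in pentagon_result.model.helices]
        assert len(set(coords)) == len(coords)

    def test_triangle_three_helices(self, triangle_result):
        assert len(triangle_result.model.helices) == 3
        assert len(triangle_result.model.minis) == 0

    def test_hybrid_mixed_footprints(self):
        """Half the edges reinforced: 4-helix and 1-helix edges coexist
        in one model."""
        mesh = generate_fixture_mesh("fan_polygon", n=6, scale=100.0)
        graph = build_edge_graph(mesh)
        half = set(range(len(graph.edges) // 2))
        res = run_pipeline(mesh, PipelineConfig(scale=0.34, reinforce=half,
                                                seed=0))
        per_edge = {}
        for h in res.model.helices:
            per_edge[h.edge] = per_edge.get(h.edge, 0) + 1
        counts = set(per_edge.values())
        assert 4 in counts and (1 in counts or 2 in counts)


class TestCadnanoIO:
    def test_write_read_write_byte_identical(self, pentagon_result, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        doc = write_cadnano(pentagon_result.model, p1)
        doc2 = read_cadnano(p1)
        write_cadnano(doc2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert doc.pointer_graph() == doc2.pointer_graph()

    def test_pointer_reciprocity_validated(self, pentagon_result, tmp_path):
        path = tmp_path / "d.json"
        write_cadnano(pentagon_result.model, path)
        read_cadnano(path)  # no error

    def test_corrupted_pointer_detected(self, triangle_result, tmp_path):
        path = tmp_path / "c.json"
        write_cadnano(triangle_result.model, path)
        obj = json.loads(path.read_text())
        for vs in obj["vstrands"]:
            for cell in vs["scaf"]:
                if cell[2] >= 0:
                    cell[3] = (cell[3] + 7) % len(vs["scaf"])  # dangle it
                    break
            else:
                continue
            break
        path.write_text(json.dumps(obj))
        with pytest.raises(CadnanoFormatError, match="cell"):
            read_cadnano(path)

    def test_empty_model_minimal_doc(self, tmp_path):
        model = StrandModel(helices=[], helix_of={}, scaffold=[], minis=[],
                            staples=[])
        doc = model_to_cadnano(model)
        path = tmp_path / "empty.json"
        write_cadnano(doc, path)
        back = read_cadnano(path)
        assert back.vstrands == []

    def test_loop_skip_arrays_zero_filled(self, pentagon_result):
        for vs in pentagon_result.doc.vstrands:
            assert set(vs["loop"]) == {0} and set(vs["skip"]) == {0}


class TestSequences:
    def test_global_complementarity(self, pentagon_result):
        """Every paired staple base is the Watson-Crick complement of the
        scaffold-side base at its position."""
        model = pentagon_result.model
        seqs = pentagon_result.sequences
        scaf_base = {}
        for s, c in zip(model.scaffold, seqs.scaffold):
            if s.helix >= 0:
                scaf_base[(s.helix, s.base)] = c
        mini_rows = [r for r in seqs.rows if r["class"] == "mini"]
        for oligo, row in zip(model.minis, mini_rows):
            for s, c in zip(oligo, row["sequence"]):
                scaf_base[(s.helix, s.base)] = c
        staple_rows = [r for r in seqs.rows if r["class"] != "mini"]
        assert len(staple_rows) == len(model.staples)
        for st, row in zip(model.staples, staple_rows):
            for s, c in zip(st.steps, row["sequence"]):
                if s.helix is None:
                    assert c == "T"
                else:
                    h = model.helix_of[s.helix]
                    assert c == COMPL[scaf_base[(h, s.base)]]

    def test_all_A_scaffold_forces_all_T_staples(self, triangle_result):
        model = triangle_result.model
        seqs = thread_sequences(model, scaffold="A" * len(model.scaffold))
        for row in seqs.rows:
            if row["class"] != "mini":
                assert set(row["sequence"]) == {"T"}

    def test_short_scaffold_budget_error(self, pentagon_result):
        with pytest.raises(BudgetError, match="scaffold"):
            thread_sequences(pentagon_result.model, scaffold="ACGT" * 10)

    def test_random_scaffold_properties(self):
        seq = random_scaffold(2000, seed=5)
        assert len(seq) == 2000 and set(seq) <= set("ACGT")
        for b in "ACGT":
            assert b * 5 not in seq
        assert random_scaffold(2000, seed=5) == seq

    def test_sequence_csv_roundtrip(self, pentagon_result, tmp_path):
        import pandas as pd
        path = tmp_path / "seqs.csv"
        pentagon_result.sequences.write_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["name", "class", "well", "length",
                                    "sequence"]
        assert (df["length"] == df["sequence"].str.len()).all()
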