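"""End-to-end design pipeline: mesh -> route -> layout -> reinforce ->
staple -> export, with a single configuration object and a machine-
readable report.

Every stage validates its invariants before the next runs; identical
inputs and seeds give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import constants as C
from .cadnano import (CadnanoDoc, SequenceTable, build_strand_model,
                      model_to_cadnano, thread_sequences, write_cadnano)
from .layout import (BudgetReport, EdgeDesign, StrainReport,
                     assign_edge_lengths, check_scaffold_budget, relax,
                     scaffold_spacer_counts, vertex_gap_nm)
from .mesh import Mesh, build_edge_graph
from .reinforce import (BundleLayout, ReinforceParams, reinforce_edge,
                        select_reinforced)
from .routing import ATrail, route, validate_atrail
from .staples import Staple, compute_t_spacers, design_staples

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """User-facing knobs of the design pipeline.

    ``reinforce`` selects edges for reinforcement: "all", "none", or an
    explicit set of edge ids; edges at or below ``threshold`` bases are
    skipped with a note in the report.  ``scaffold_seq`` may hold an
    explicit scaffold sequence (e.g. p7560); otherwise a seeded random
    scaffold of exactly the consumed length is threaded, while
    ``scaffold_length`` is still checked as the budget.
    """
    scale: float = 1.0
    reinforce: str | set[int] = "all"
    threshold: int = C.REINFORCE_THRESHOLD
    scaffold_seq: str | None = None
    scaffold_length: int = C.DEFAULT_SCAFFOLD_LENGTH
    seed: int = 0
    relax_iters: int = 200
    relax_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")


@dataclass
class PipelineResult:
    mesh: Mesh
    graph: object
    trail: ATrail
    doubled: list[int]
    designs: list[EdgeDesign]
    bundles: dict[int, BundleLayout]
    staples: list[Staple]
    model: object
    doc: CadnanoDoc
    sequences: SequenceTable
    strain: StrainReport
    budget: BudgetReport
    skipped: list[int]
    log: list[str] = field(default_factory=list)

    def report(self) -> dict:
        hist = Counter(st.length for st in self.staples)
        return {
            "edges": len(self.graph.edges),
            "doubled_edges": self.doubled,
            "reinforced_edges": sorted(self.bundles),
            "skipped_below_threshold": self.skipped,
            "scaffold_used": self.budget.used,
            "scaffold_available": self.budget.available,
            "scaffold_ok": self.budget.ok,
            "n_staples": len(self.staples),
            "n_mini_oligos": len(self.model.minis),
            "staple_length_histogram": dict(sorted(hist.items())),
            "helices_per_reinforced_edge": {
                e: len(b.ring) for e, b in sorted(self.bundles.items())},
            "final_max_strain": self.strain.max_relative_strain,
        }


def _stage(log: list[str], name: str, payload) -> None:
    digest = hashlib.sha256(
        repr(payload).encode("utf-8", errors="replace")).hexdigest()[:12]
    log.append(f"{name}: {digest}")


def run_pipeline(mesh: Mesh, config: PipelineConfig) -> PipelineResult:
    """Run the full design procedure on a mesh.

    Raises the originating stage's error (nothing is written by this
    function; callers persist outputs only on success).
    """
    log: list[str] = []
    mesh.validate()
    graph = build_edge_graph(mesh)
    _stage(log, "mesh", (mesh.n_vertices, mesh.n_faces))

    designs = assign_edge_lengths(mesh, config.scale, graph)
    designs, strain, relaxed_pos = relax(
        designs, mesh, scale=config.scale, graph=graph,
        max_iter=config.relax_iters, tol=config.relax_tol)
    relaxed_mesh = Mesh(vertices=relaxed_pos, faces=mesh.faces)
    _stage(log, "layout", [d.length_bp for d in designs])

    trail, egraph, doubled = route(graph, seed=config.seed)
    rep = validate_atrail(egraph, trail)
    if not rep.ok:
        raise AssertionError(f"internal: invalid A-trail {rep.violations}")
    designs = [replace(d, is_double=(d.edge in set(doubled)))
               for d in designs]
    _stage(log, "route", [(s.edge, s.copy) for s in trail.steps])

    params = ReinforceParams(threshold=config.threshold)
    if config.reinforce == "all":
        requested: set[int] | None = None
    elif config.reinforce == "none":
        requested = set()
    else:
        requested = set(config.reinforce)
    designs, skipped = select_reinforced(designs, requested, params)
    bundles = {d.edge: reinforce_edge(d, params)
               for d in designs if d.reinforced}
    _stage(log, "reinforce", sorted(bundles))

    def gap_fn(v: int, ea: int, eb: int) -> int:
        if ea == eb:
            return 0
        return compute_t_spacers(vertex_gap_nm(relaxed_mesh, egraph, v,
                                               ea, eb))

    staples = design_staples(egraph, designs, bundles, gap_fn)
    _stage(log, "staple", len(staples))

    spacers = scaffold_spacer_counts(trail, relaxed_mesh, egraph)
    budget = check_scaffold_budget(
        designs, trail, {d.edge for d in designs if d.reinforced},
        scaffold_length=config.scaffold_length, spacer_counts=spacers)
    model = build_strand_model(egraph, trail, designs, bundles, staples,
                               spacer_counts=spacers)
    if config.scaffold_seq is not None and \
            len(config.scaffold_seq) < model.scaffold_bases_used():
        from .errors import BudgetError
        raise BudgetError(
            f"provided scaffold ({len(config.scaffold_seq)} nt) shorter "
            f"than the {model.scaffold_bases_used()} bases used")
    sequences = thread_sequences(model, scaffold=config.scaffold_seq,
                                 seed=config.seed)
    doc = model_to_cadnano(model)
    _stage(log, "export", len(doc.vstrands))

    return PipelineResult(
        mesh=mesh, graph=egraph, trail=trail, doubled=doubled,
        designs=designs, bundles=bundles, staples=staples, model=model,
        doc=doc, sequences=sequences, strain=strain, budget=budget,
        skipped=skipped, log=log)


def write_outputs(result: PipelineResult, outdir: str | Path,
                  stem: str = "design") -> dict[str, Path]:
    """Persist the caDNAno JSON, sequence CSV and report; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cadnano": outdir / f"{stem}.json",
        "sequences": outdir / f"{stem}_sequences.csv",
        "report": outdir / f"{stem}_report.json",
    }
    write_cadnano(result.doc, paths["cadnano"])
    result.sequences.write_csv(paths["sequences"])
    paths["report"].write_text(
        json.dumps({"report": result.report(), "log": result.log},
                   indent=2, sort_keys=True))
    return paths
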