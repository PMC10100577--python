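# wirebundle

Top-down design of wireframe DNA origami whose edges are stiffened into
square-lattice **four-helix bundles (4HB)**, plus the filament-stiffness
analysis used to quantify the result.

## Who this is for

DNA nanotechnologists who describe a target 2D or 3D shape as a polygonal
mesh (PLY) and want, at the end, a caDNAno JSON file and a table of staple
and mini-scaffold sequences ready to order — and biophysicists who digitize
filament traces from TEM images and want a persistence length out of them.

## What it does

**Design pipeline** (`mesh → route → layout → reinforce → staple → export`):

1. **A-trail routing.** The mesh's edge graph is made Eulerian by adding a
   minimum set of "double edges" (a minimum T-join over the odd-degree
   vertices), then a scaffold circuit is found that traverses every edge
   exactly once such that consecutive edges are always neighbours in the
   cyclic ordering around their shared vertex — an *A-trail* — so the
   scaffold never crosses itself at a vertex.
2. **Layout.** Geometric edge lengths become whole-base helix lengths
   (0.34 nm/bp), followed by a damped spring relaxation that minimizes the
   strain introduced by rounding.
3. **Reinforcement.** Each selected edge with more than ~30 bases receives
   two additional scaffold helices: a loop extruded from the main helix at
   a double crossover and closed by end-loops, slightly shorter than the
   edge. A fourth helix of the same length as the edge is built from
   **mini-scaffolds** — synthetic 30–60 nt strands not connected to the
   scaffold. Edges that were doubled during routing get only the loop pair:
   the 4HB is then the double edge plus the two loops. Hybrid structures
   (some edges flexible, some rigid) come from partial selections.
4. **Staples.** Two classes: *vertex staples* (30–60 nt, one arm on each of
   two rotation-adjacent edges, unpaired T spacers bridging the vertex gap)
   and modular *bundle staples* (interior staples of exactly 32 nt with a
   single 16-base seed, weaving between lattice-adjacent helices).
5. **Export.** A single closed scaffold circuit, every staple and mini
   oligo, and the per-base pairing map are assembled and checked (every
   double-helical position claimed exactly once per side), then written as
   square-lattice caDNAno JSON plus a sequences CSV. Output is
   byte-reproducible for fixed seeds.

**Stiffness analysis.** Spines are resampled at 11 nm arc-length spacing;
the mean cosine between tangents separated by contour length *l* is fitted
to the worm-like-chain decay

    ⟨cos θ(l)⟩ = exp(−l / (s·p))

with surface parameter *s* = 2 for filaments equilibrated on a surface,
yielding the persistence length *p*. A seeded 2D WLC simulator generates
validation ensembles with exactly this decay.

## Worked example

Design a 2D pentagonal mesh with 100 bp rim edges, all edges reinforced:

```sh
wirebundle mesh fixture fan_polygon --n 5 --scale 10.0 --out pentagon.ply
wirebundle run pentagon.ply --scale 2.8926 --seed 1 --out-dir out/
```

prints (abridged):

```json
{
  "doubled_edges": [0, 5, 8],
  "edges": 10,
  "helices_per_reinforced_edge": {"0": 4, "1": 4, "...": 4, "9": 4},
  "n_mini_oligos": 14,
  "n_staples": 102,
  "scaffold_used": 2785,
  "scaffold_available": 7560,
  "scaffold_ok": true,
  "staple_length_histogram": {"16": 8, "20": 2, "21": 4, "32": 47,
                              "34": 6, "35": 2, "36": 8, "37": 9,
                              "42": 1, "48": 5, "50": 10}
}
```

Reading this: the pentagon's six odd-degree vertices forced 3 double edges
(`doubled_edges`); every edge carries a 4-helix bundle; the scaffold circuit
consumes 2785 of the default 7560-base scaffold, so the design folds from a
p7560-sized strand; 47 staples are the 32-base modular bundle staples and
the longer ones are vertex staples and terminal caps. `out/design.json`
opens in caDNAno; `out/design_sequences.csv` lists every staple and mini
oligo, e.g.

```
name,class,well,length,sequence
mini_000,mini,,43,TCGCTTTGCCTCCAATGAATCACCCCACATGCGGTGGCGGTGA
...
```

Analyze simulated traces at the two stiffness scales typical for a
single-helix rod versus a reinforced rod:

```sh
wirebundle simulate-wlc --p 1730 --chains 100 --points 50 --seed 2 --out traces.csv
wirebundle analyze-pl traces.csv            # → persistence_length_nm ≈ 1700
```

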