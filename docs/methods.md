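# Methods

This note records the models, conventions and design choices behind
`wirebundle`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the package had to fix details that the
underlying design rules leave open.

## Mesh model and rotation system

A target shape is a polygonal mesh (vertices + faces). Faces are first
re-oriented coherently by a breadth-first walk over shared edges
(non-orientable input is rejected); each oriented face corner `a → v → b`
then declares edge (v,b) the rotation successor of edge (v,a) at `v`.
Closed vertices yield a cyclic rotation, boundary vertices of 2D meshes an
open fan in the same order. This rotation system is the combinatorial
embedding that defines A-trail adjacency; everything downstream depends
only on it, not on coordinates.

The PLY reader is intentionally minimal (ASCII and binary-little-endian,
`vertex` x/y/z and `face` vertex_indices, extra properties skipped). A
general-purpose mesh library was not used for parsing because common ones
re-triangulate polygonal faces on load, which would alter the edge graph.

## Eulerianization and A-trail search

Odd-degree vertices are paired by a minimum-weight perfect matching under
shortest-path distance; the symmetric difference of the matched paths is a
minimum T-join, and doubling those edges makes every degree even with a
provably minimal number of added helices. The doubled copy is inserted
adjacent to its sibling in both rotations, reflecting that a double edge is
physically a parallel helix pair.

A-trail existence is NP-hard in general, but wireframe meshes are small.
The search is depth-first backtracking in which, at each vertex visit, only
the two rotation neighbours of the incoming edge instance are candidate
continuations; the closure constraint between the last and first edge is
enforced before accepting a circuit. Candidate order is fixed and the seed
permutes only the starting edge, so results are reproducible. If a doubling
placement admits no A-trail, the driver retries alternative minimum
doubling sets (up to 8 by default) before failing with the explored-state
count. An independent exhaustive enumerator (tests) cross-checks existence
on all fixtures up to 30 edges.

## Lengths, relaxation, budget

Conversions use the B-DNA rise of 0.34 nm/bp throughout; the printed
pairs 100 bp ↔ 34 nm, 80 bp ↔ 27 nm and 230 bp ↔ 78 nm are all consistent
with it. Rounding to whole bases strains the geometry, so vertex positions
are relaxed by gradient descent with a halving line search on the spring
energy Σ((l−r)/r)², which makes the reported strain series non-increasing
by construction — this is a contract, not a claim of mechanical realism;
the original design software's physics engine is not reproduced. After
relaxation edge lengths are re-rounded once.

The scaffold budget counts main helices (doubled edges twice), the two
loop helices of every reinforced edge, and vertex spacer bases; mini
scaffolds are synthesized separately and never count. The default budget
is 7560 bases (a p7560-class scaffold); by default the threaded scaffold
is a seeded random sequence of exactly the consumed length with 50% GC and
no homopolymer longer than 4, so designs remain testable offline.

## Four-helix bundle construction

Footprint on the 2×2 square lattice: main (0,0), loopA (1,0), loopB (1,1),
mini (0,1); for an originally doubled edge the second scaffold helix takes
the mini slot and no mini helix exists. Scaffold-side strand directions
alternate (+,−,+,−) around this ring so that every lattice-adjacent pair is
antiparallel.

Crossover admissibility follows square-lattice convention: positions
repeat mod 8 with per-neighbour offsets (scaffold double crossovers
main↔loopA at 3 mod 8, end-loops and staple crossovers at 0/7 mod 8) and a
32-base super-period. Loop helices span between the outermost admissible
end-loop positions at least 5 bases inside the edge ends — the concrete
realization of "slightly shorter than the main edge, limited by the
possible location of crossovers".

The scaffold excursion enters loopA at the double-crossover site nearest
the edge midpoint, runs to the near end-loop, traverses loopB fully,
returns along loopA's other segment and re-enters the main helix at the
paired position. Exactly one *scaffold* double crossover is used per edge:
a second main↔loopA double crossover provably splits the scaffold into two
circuits (each double crossover's two exchanges close off a separate
cycle), which would break the single-circuit requirement. Edges long
enough to earn additional double crossovers (one per further 96 bases —
three super-periods, keeping spacing regular) have them realized in the
staple layer, whose modular weave crosses main↔loopA every 16 bases and
rigidly couples the helices at those sites.

Mini helices have exactly the edge length and are split into
`ceil(L/60)` oligos, as even as possible (lengths differing by ≤ 1), which
keeps every piece within the 30–60 base synthesis window for any L ≥ 30.
Mini nicks fall where the even split puts them; they are not specially
offset from staple-side nicks, since nicks on opposite strands of the same
column are not a coincident weak point.

## Staple design

Interior bundle staples are 32 bases in an 8+16+8 domain pattern: within
each 32-base super-period, four staples (one seed per helix, offsets 0, 16,
0, 16) cover each helix's four 8-base slots exactly once, with all
crossovers at admissible columns. Regions outside the tiling window —
loop-helix ends, mini ends, main-helix remainders between the tiling and
the vertex arms — are covered by terminal staples (flagged non-interior,
14–60 bases). Loop caps pair loopA/loopB column intervals; a cap segment
whose boundary is an end-loop column *crosses* between the loop helices
there instead of nicking, and piece boundaries are nudged so that no bundle
staple nick lands on a scaffold crossover or end-loop column (this is
verified, not assumed — violation raises an error). Main remainders shorter
than 14 bases are absorbed into the adjacent interior staple when a tiling
exists, else into the innermost vertex arm.

Vertex staples clamp edge ends with one 16-base arm per edge and T spacers
between arms; the spacer count is `round(gap/0.4 nm)` clamped to [0, 5],
with the gap estimated as helix radius (1 nm) times the angle between the
two edges at the relaxed vertex — a concrete reading of "a few unpaired
bases", using the ~0.4 nm/nt contour of ssDNA. Arm capacity per edge end:
two arms for edges ≥ 96 bp, one for 37–95 bp, none below 37 bp; edges too
short for arms are spanned *pass-through* by a single staple whose arms sit
on rotation-neighbour edges (arm length adapted so the staple stays ≤ 60
bases). This keeps every vertex staple within 30–60 bases even for 20 bp
edges, where two 10-base arms alone would fall below 30. At each vertex,
rotation-adjacent pairs are stapled greedily so that every end with
capacity is clamped at least once; ends with two arms also close the
remaining adjacent pairs (a degree-4 vertex of long edges gets four vertex
staples, one per adjacent pair). The two copies of a doubled edge are
rotation-adjacent and are spanned by a vertex staple like any pair.

Strand polarity bookkeeping is simplified: staples are recorded in a
canonical per-edge frame (antiparallel to the scaffold-side direction of
each helix) rather than tracking global 5′→3′ orientation through vertex
jumps. Pairing, occupancy, lengths and sequences are unaffected; only the
listed step order of some vertex staples differs from a strict polarity
trace.

## Strand model, caDNAno, sequences

Each edge owns a distinct 2×2 block of lattice slots (rows 0–1, columns
2e, 2e+1). The global model is validated against a per-base occupancy map:
every base of every helix span must be claimed exactly once on the
scaffold side (scaffold circuit or a mini oligo) and exactly once on the
staple side. The caDNAno document is the square-lattice JSON flavour with
reciprocal 4-tuple pointers and zero-filled loop/skip arrays; serialization
sorts keys and fixes separators so write→read→write is byte-identical.
Scaffold threading starts at the first base of the lowest-numbered helix;
staple colors encode class. Paired staple bases take the Watson–Crick
complement of whatever scaffold-side strand occupies their position;
designed spacers are T; unpaired scaffold bases at vertices consume
scaffold sequence like any others.

## Stiffness analysis

Digitized traces (ordered 2D points, nm) are resampled at 11 nm arc-length
spacing along the piecewise-linear spine. Tangent vectors between adjacent
spine points give, for each contour separation l, the pooled mean cosine;
the decay model `⟨cos θ⟩ = exp(−l/(s·p))` with s = 2 (surface-equilibrated
chains) is fitted by weighted least squares on the log, through the
origin, restricted to separations with mean cosine > 0.3 (the log of
near-zero noise is uninformative) and at least 10 tangent pairs. Only the
product s·p is identifiable; s is a stated convention. Noiseless model
input is inverted to machine precision; correlations that do not decay
(free-intercept trend ≥ 0) return an infinite-p sentinel with a diagnostic
rather than a spurious estimate.

The WLC simulator draws independent Gaussian turn angles of variance
(spacing/p) per step in 2D, which gives exactly the s = 2 decay; it
emulates the *geometry* of surface-equilibrated filament traces, not
imaging noise, digitization error, finite filament width or excluded
volume. Parameter recovery tests (100 chains × 50 points at 11 nm, fixed
seed, within 15% for p ∈ {200, 461, 1000, 1730} nm) therefore demonstrate
estimator correctness at the stiffness scales of interest, not robustness
to TEM artefacts.

Vertex-to-vertex distance statistics are plain per-group mean/sd/n with a
monotonicity flag across the designed-length ordering.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
fixture meshes up to the icosahedron (30 edges, 36 after doubling) and a
3-segment rod; the design library spans edge lengths 40–230 bp; WLC
ensembles are 100 chains of 50 points. All of it completes in seconds.

## Known limitations

* The vertex-staple policy needs at least one arm-capable (≥ 37 bp) edge
  adjacent to every short edge; meshes made entirely of sub-37 bp edges
  cannot be stapled and fail loudly.
* Relaxation is a spring model on vertex positions; it does not model
  torsional strain, groove phasing at vertices, or sequence-dependent
  mechanics.
* No steric checking beyond end margins: reinforcing every edge of a
  vertex with many incident edges may clash physically even though the
  design is combinatorially valid.
* A-trail search is exponential in the worst case; a state cap (5×10⁶)
  turns pathological inputs into explicit failures.
* caDNAno output aims at schema validity and reciprocity, not at matching
  any particular GUI's cosmetic conventions (colors, scaffold seam).
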