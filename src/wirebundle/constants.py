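"""Physical constants and lattice conventions shared across modules.

All base-pair <-> length conversions use the B-DNA rise.  The crossover
conventions follow square-lattice caDNAno tooling: positions repeat with
period 8 with a per-neighbour-direction offset, and 32 bases form one
super-period (one staple module).
"""

#: B-DNA helical rise, nm per base pair.
RISE_NM = 0.34

#: Contour length of one unpaired (single-stranded) nucleotide, nm.
SS_NT_NM = 0.4

#: Maximum number of unpaired T bases inserted at a vertex gap.
MAX_T_SPACERS = 5

#: Effective helix radius used for vertex gap estimates, nm.
HELIX_RADIUS_NM = 1.0

#: Staple module length (one square-lattice super-period), bases.
STAPLE_MODULE = 32

#: Seed length of an interior bundle staple, bases.
STAPLE_SEED = 16

#: Crossover period on the square lattice, bases.
XOVER_PERIOD = 8

#: Offset (mod 8) of scaffold double-crossover sites (main <-> loopA).
SCAFFOLD_XOVER_OFFSET = 3

#: Offset (mod 8) of loop end-loop positions (loopA <-> loopB).
ENDLOOP_OFFSET = 7

#: Default reinforcement threshold: edges need MORE than this many bases.
REINFORCE_THRESHOLD = 30

#: Edge length of the default scaffold (p7560), bases.
DEFAULT_SCAFFOLD_LENGTH = 7560

#: Mini-scaffold oligo length bounds (synthesis window), bases.
MINI_OLIGO_MIN = 30
MINI_OLIGO_MAX = 60

#: Vertex staple total-length bounds, bases (spacers included).
VERTEX_STAPLE_MIN = 30
VERTEX_STAPLE_MAX = 60

#: Vertex staple arm length bounds, bases.
ARM_MIN = 10
ARM_MAX = 31

#: Default vertex staple arm length, bases.
ARM_DEFAULT = 16

#: Shortest permitted terminal (non-interior) staple, bases.
TERMINAL_STAPLE_MIN = 14

#: Loop helix ends stay at least this many bases inside the main helix ends.
LOOP_END_MARGIN = 5
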