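# Methods

## Model

`maptig` treats assembly as a graph-cleaning problem. The overlap graph
is bidirected: every read contributes vertices `(r, +)` and `(r, −)`,
and every edge `(u, v)` coexists with its mirror `(v̄, ū)` carrying the
same overlap length. All construction and cleaning operations preserve
this invariant (asserted by `check_mirror_symmetry`), so every path has
a reverse-complement mirror path and each unitig is reported once.

The linkage map induces the colour order. A colour is a
`(chromosome, bin ordinal)` pair; two colours are *within distance d*
when they share a chromosome and their ordinals differ by at most `d`.
Chromosomes are independent linear orders, so cross-chromosome colours
are never within any distance — this is what lets the cleaning cut
chromosome-joining misassemblies even with `d` large.

Cleaning deletes every edge whose two (non-empty) endpoint colour sets
contain no pair within distance `d`. Edges with an uncoloured endpoint
are never deleted: the inconsistency definition quantifies over existing
colours, and an empty set is absence of evidence, not evidence of a bad
join. For the same reason uncoloured vertices count as consistent
neighbours in the colour-consistent degree used by unitig extraction.

Under the idealised conditions — every read correctly coloured, every
non-endpoint read with at least one genomic in- and out-edge — removing
all inconsistently coloured edges leaves only rainbow unitigs: any
surviving spurious edge joins consistently coloured reads, which forces
a branch at one endpoint, and a unitig never crosses a branch. The
test suite asserts this property over 20 simulation seeds.

## Parameters

| parameter | default | meaning |
|---|---|---|
| extension cap | 250 bp | maximum per-side stretch of a mapping toward whole-read coverage; bounded because insertions dominate long-read error, so the read is usually longer than the genomic segment it covers |
| block size | 10 000 bp | width of the marker-lookup blocks; affects speed only — colouring output is block-size independent (tested) |
| `d` | 1 | colour distance tolerated across an edge; real maps have locally noisy bin boundaries, and results are nearly flat for `d` in 0..3 (tested) |
| propagation depth | 10 | BFS depth bound; deeper searches over-approximate colour sets for unmapped reads |
| conflict gap | 2 | a propagated colour set missing ≥ 2 consecutive ordinals between its extremes (or mixing chromosomes) gets its read removed; a single missing ordinal is within the `d = 1` slack |
| min overlap | 2000 bp | shortest usable suffix–prefix overlap (standard OLC default) |
| overhang fuzz | 1000 bp | tolerance in overlap triage (internal-match rejection, transitive-reduction layout consistency) |
| tip length | 4 reads | longest dead-end branch clipped during simplification |

## Overlap triage

All-vs-all PAF records are classified by their unaligned overhangs, with
the target's coordinates re-oriented when the strands differ. If the
overhang inside the overlap exceeds `min(1000 bp, 0.8 × span)` the
record is an internal match and is dropped. Otherwise a read whose
overhangs are dominated on both sides is contained and is removed with
all its overlaps, before any edge is added; the remaining records are
dovetails and become edges in the direction the overhangs dictate.
Edge overlap lengths are clamped below both read lengths so every edge
can be spelled even when indel-driven length drift makes the projected
overlap slightly longer than a read.

## Propagation semantics

Propagation is a single simultaneous pass: only the mapping-derived
colouring seeds the search, and freshly propagated reads never colour
each other. This makes the operation idempotent and independent of read
order; reads coloured by an earlier propagation are re-derived from the
same seeds on a re-run. Conflict removal examines propagated reads
only — a directly coloured read got all its colours from one mapped
locus, so its set cannot skip genome.

## Unitig extraction

A unitig edge requires colour-consistent out-degree 1 at its source,
colour-consistent in-degree 1 at its target, endpoint consistency, and
a colour step that does not "cross" (the colour interval may move up,
down, or stay; it may not widen in both directions at once). This edge
set is mirror-symmetric, so maximal paths arrive in mirror pairs.

Where a path's colour direction strictly reverses, both strict edges
flanking the reversal are cut — cutting both keeps the rule symmetric
under mirroring, at the cost of isolating the read at the turning
point. Each piece is then reported once, oriented so its colours are
non-decreasing; pieces whose colours do not decide (uncoloured or flat)
take the orientation with the lexicographically smaller first vertex.
Cycles are canonicalized to the smallest rotation over both
orientations. With no colours anywhere, all colour conditions are
vacuous and the procedure is exactly the classical
maximal-non-branching-path algorithm.

A note on "rainbow": with a dense map a correctly coloured read carries
a *range* of tens of consecutive bin colours, and overlapping reads
share most of them. The single-colour notion of a rainbow path (no
colour reused except by consecutive vertices) is therefore unsatisfiable
verbatim; the property actually guaranteed, and the one the tests
assert, is its interval generalisation — all colours on one chromosome,
interval bounds non-decreasing along the path, and consecutive sets
sharing or adjoining a colour.

## The simulator

The generator emulates the conditions the method is designed for, not
real sequencers:

* genome: uniform random bases, several chromosomes, no engineered
  repeats — so a repeat-induced spurious overlap must be injected
  explicitly rather than arising from sequence;
* linkage map: markers uniform at random at 0.008/bp; a new bin starts
  when the gap from the previous marker reaches 200 bp, giving
  ~0.002 bins/bp and inter-bin spacing ≥ 200 bp. The genome acts as its
  own draft assembly, isolating the guided cleaning from draft quality;
* reads: uniform starts, truncated-normal lengths (default 15 kb ± 3 kb,
  40×), i.i.d. per-base errors at 10% with an insertion : deletion :
  substitution mix of 6 : 2 : 2. No error-length autocorrelation, no
  chimeras, no quality values;
* true alignments and overlaps come from the recorded read origins;
  read-coordinate projections are scaled for indel length drift.
  Injected spurious overlaps are fabricated dovetails between reads
  whose acceptable colour ranges are ≥ `min_sep_bins` ordinals apart
  (or on different chromosomes), restricted to reads that survive
  containment triage so every injected edge actually reaches the graph.

Because the genome is repeat-free and alignments are truth-derived,
passing tests demonstrate the correctness of the colouring, cleaning
and extraction logic — not robustness to mapper error, repeats, or
heterozygosity, which real data adds on top.

## Problem sizes

The acceptance script simulates 2 × 1 Mbp at 40× (≈ 5300 reads,
≈ 9000 graph edges) and completes in well under a minute; the test
suite's end-to-end checks use 2 × 500 kb for the same pipeline and
60–200 kb genomes elsewhere. These sizes keep every quantity
(coverage, densities, read lengths) at the study's values while holding
the whole suite to a few seconds.

## Known limitations

* One longest mapping per read: a read spanning a draft misjoin gets
  the colours of only one side; the conflict filter and edge cleaning
  are the backstop.
* The uniform error model is calibrated for coordinate bookkeeping, not
  for base-level realism; consensus polishing is out of scope.
* Colour-guided joining of unitigs into chromosome-scale contigs is not
  implemented; unitig colour ranges are reported (`cl:Z:` tags) to make
  that ordering possible downstream.
* GFA support covers the S/L subset with `<n>M` overlaps that OLC
  tools exchange, not the full specification.
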