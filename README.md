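# maptig

Linkage-map-guided cleaning of long-read overlap graphs, with guided
(rainbow-path) unitig extraction.

## The problem

Overlap–layout–consensus assembly of noisy long reads (PacBio, Nanopore)
builds a directed *overlap graph*: two vertices per read (one per
orientation) and an edge for every suffix–prefix overlap, each edge
mirrored by its reverse-complement twin. Sequencing error and repeats
put *spurious* edges in this graph — overlaps between reads that come
from distant parts of the genome — and a single spurious edge used in a
contig is a misassembly.

A dense **linkage map** provides exactly the long-range information the
reads lack. It is a set of markers localised on draft-assembly contigs,
grouped into *bins* of co-segregating markers; bins are assigned to
chromosomes and totally ordered within each chromosome. A bin's rank in
that order is a **colour**, and a read that maps over a marker inherits
the marker's bin colour. The *coloured overlap graph* is the overlap
graph `G = (V, E)` together with a colouring `c : V → P(ℕ)` mapping each
vertex to a set of colours.

`maptig` cleans the graph with the colours:

1. **colour** — map reads to any draft assembly (minimap2 PAF, or the
   built-in simulator's true alignments); keep each read's longest
   mapping, stretch it toward whole-read coverage (capped at 250 bp per
   side, because long-read error is insertion-dominated), index the
   stretched intervals in fixed-width blocks, and give each read the
   colours of all markers inside its interval.
2. **propagate** — reads with no mapping are coloured by a
   breadth-first search over the graph (depth ≤ 10) that traverses only
   uncoloured reads and unions the colour sets of the coloured reads it
   first reaches. Reads whose propagated colours skip part of a
   chromosome, or mix chromosomes, are removed.
3. **clean** — an edge `(v_i, v_j)` is *inconsistently coloured* when no
   pair of colours `c_i ∈ c(v_i)`, `c_j ∈ c(v_j)` satisfies
   `|c_i − c_j| ≤ d` (default `d = 1`; colours on different chromosomes
   are never within any distance). All inconsistently coloured edges
   are deleted; standard transitive reduction and tip clipping follow.
4. **unitig** — maximal unambiguous paths are read off using
   *colour-consistent degrees*: `deg_c⁻(v)` counts only in-neighbours
   with at least one colour equal or adjacent to a colour of `v` (and
   symmetrically `deg_c⁺`). Along a path the colour intervals must
   advance monotonically through the map order, so every reported
   unitig is a *rainbow unitig*: colours confined to one chromosome and
   non-decreasing, repeats allowed only between neighbouring reads.
   On an uncoloured graph this reduces exactly to the classical unitig
   algorithm.

A synthetic-data generator (random multi-chromosome genome, dense map at
~0.008 markers/bp and ~0.002 bins/bp, insertion-biased reads with known
origins, true alignments and overlaps, optional injected spurious
overlaps) makes the whole pipeline testable without any downloads.

## Worked example

```
$ maptig simulate --n-chrom 1 --chrom-len 200000 --coverage 20 \
      --mean-len 8000 --len-sd 1500 --min-overlap 1000 \
      --spurious-n 10 --seed 7 --outdir sim
simulated 500 reads over 1 x 200000 bp, 1600 markers in 334 bins -> sim
$ maptig colour --paf sim/alignments.paf --map sim/map.tsv -o colours.tsv
coloured 500/500 reads -> colours.tsv
$ maptig graph --ava sim/overlaps.paf --colours colours.tsv \
      --min-overlap 1000 -o coloured.gfa
graph: 166 reads, 1112 overlap edges -> coloured.gfa
$ maptig clean --gfa coloured.gfa -d 1 -o cleaned.gfa --report report.tsv
cleaned: 10 inconsistent edges, 0 conflicting reads removed; 165/1112 edges kept -> cleaned.gfa
$ maptig unitig --gfa cleaned.gfa --reads sim/reads.fq -o unitigs.fa \
      --gfa-out unitigs.gfa
1 unitigs, total 207514 bp, N50 207514 bp
```

What happened: 500 simulated reads (334 of them contained in longer
reads and removed during overlap triage) gave a 166-read graph with
1112 edges, including the 10 injected spurious overlaps joining reads
at least 5 bins apart. Cleaning at `d = 1` deleted exactly those 10
inconsistently coloured edges; transitive reduction then thinned the
redundant genomic edges down to the 165-edge backbone, and the single
chromosome came out as a single unitig covering the whole 200 kb
(207.5 kb of sequence — raw reads carry ~4% net length inflation from
insertion errors). The FASTA header carries the unitig's colour range:

```
>utg000001 LN:i:207514  cl:Z:0,333
```

Scoring against the simulation truth:

```
$ maptig evaluate --truth sim/truth.tsv --map sim/map.tsv \
      --colours colours.tsv --gfa cleaned.gfa -o eval.json
```

reports 100% of reads coloured fully inside their acceptable colour
ranges (the range between the last marker before a read's true origin
and the first marker after it) and 0 spurious edges surviving in the
cleaned graph.

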