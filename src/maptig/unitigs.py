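"""Guided unitig extraction from the cleaned coloured overlap graph.

A unitig is a maximal unambiguous path.  In the guided setting the
degree conditions are evaluated on *colour-consistent* neighbours only
(neighbours with at least one colour equal or adjacent to the vertex's
own), and the colours along a path must advance monotonically through
the map order — a path whose colour interval jumps backwards and
forwards cannot spell a single genomic segment.  On a graph with no
colours at all every colour condition is vacuous and extraction reduces
exactly to the classical maximal-non-branching-path unitig algorithm.

Because the graph holds both orientations of every read, every path has
a reverse-complement mirror path; each unitig is reported once, in the
orientation in which its colours are non-decreasing (lexicographically
smallest first vertex when the colours do not decide).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .linkage_map import Colour
from .overlap_graph import (
    ColouredOverlapGraph,
    Vertex,
    colour_sets_consistent,
    flip,
)

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class AssemblyError(ValueError):
    """Raised when an overlap length is incompatible with its reads."""


@dataclass
class Unitig:
    """An extracted unitig: vertex path plus per-vertex colour sets."""

    path: list[Vertex]
    colour_list: list[frozenset[Colour]] = field(default_factory=list)
    sequence: str | None = None

    @property
    def name_hint(self) -> str:
        return f"{self.path[0][0]}..{self.path[-1][0]}"

    def colour_range(self) -> tuple[Colour, Colour] | None:
        """(min, max) colour over the whole path, None if uncoloured."""
        all_colours = sorted({c for cs in self.colour_list for c in cs})
        if not all_colours:
            return None
        return all_colours[0], all_colours[-1]

    def __len__(self) -> int:
        return len(self.path)


# ---------------------------------------------------------------------
# Colour step direction between consecutive path vertices
# ---------------------------------------------------------------------

def _colour_step(a: set[Colour], b: set[Colour]) -> str:
    """Direction of the colour interval from a to b.

    Returns ``"up"``, ``"down"``, ``"flat"``, ``"none"`` (an endpoint is
    uncoloured or the sets share no chromosome), or ``"cross"`` when the
    intervals move in opposite directions at once — the only step a
    unitig may never take.
    """
    if not a or not b:
        return "none"
    by_chrom_a: dict[int, tuple[int, int]] = {}
    for c in a:
        lo, hi = by_chrom_a.get(c.chromosome_index, (c.ordinal, c.ordinal))
        by_chrom_a[c.chromosome_index] = (min(lo, c.ordinal), max(hi, c.ordinal))
    directions: set[str] = set()
    shared = False
    for c in b:
        if c.chromosome_index not in by_chrom_a:
            continue
        shared = True
    if not shared:
        return "none"
    by_chrom_b: dict[int, tuple[int, int]] = {}
    for c in b:
        lo, hi = by_chrom_b.get(c.chromosome_index, (c.ordinal, c.ordinal))
        by_chrom_b[c.chromosome_index] = (min(lo, c.ordinal), max(hi, c.ordinal))
    for chrom, (blo, bhi) in by_chrom_b.items():
        if chrom not in by_chrom_a:
            continue
        alo, ahi = by_chrom_a[chrom]
        if blo >= alo and bhi >= ahi:
            directions.add("flat" if (blo, bhi) == (alo, ahi) else "up")
        elif blo <= alo and bhi <= ahi:
            directions.add("down")
        else:
            return "cross"
    strict = directions - {"flat"}
    if len(strict) > 1:
        return "cross"
    if strict:
        return strict.pop()
    return "flat"


# ---------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------

def _unitig_edges(
    graph: ColouredOverlapGraph, d: int
) -> dict[Vertex, Vertex]:
    """The edges a unitig may traverse, as a successor map.

    Edge (u, v) qualifies when u's colour-consistent outdegree and v's
    colour-consistent indegree are both exactly 1, the edge itself joins
    consistent colour sets, and the colour interval does not cross.
    The qualifying set is mirror-symmetric, so paths come in mirror
    pairs.
    """
    dist = max(1, d)
    cc_in: dict[Vertex, int] = {}
    cc_out: dict[Vertex, int] = {}
    for v in graph.g.nodes:
        cv = graph.colour_of(v)
        cc_in[v] = sum(
            1
            for u in graph.g.predecessors(v)
            if colour_sets_consistent(cv, graph.colour_of(u), dist)
        )
        cc_out[v] = sum(
            1
            for w in graph.g.successors(v)
            if colour_sets_consistent(cv, graph.colour_of(w), dist)
        )
    succ: dict[Vertex, Vertex] = {}
    for u, v, _ in graph.edges():
        if cc_out[u] != 1 or cc_in[v] != 1:
            continue
        cu, cv = graph.colour_of(u), graph.colour_of(v)
        if not colour_sets_consistent(cu, cv, dist):
            continue
        if _colour_step(cu, cv) == "cross":
            continue
        succ[u] = v
    return succ


def _split_on_direction(
    graph: ColouredOverlapGraph, path: list[Vertex]
) -> list[list[Vertex]]:
    """Cut a path so every piece advances in one colour direction.

    At each reversal both flanking strict edges are cut, so the rule is
    invariant under mirroring the path and forward/mirror traversals
    split identically.
    """
    if len(path) < 2:
        return [path]
    steps = [
        _colour_step(graph.colour_of(a), graph.colour_of(b))
        for a, b in zip(path, path[1:])
    ]
    strict = [i for i, s in enumerate(steps) if s in ("up", "down")]
    cut: set[int] = set()
    for prev, cur in zip(strict, strict[1:]):
        if steps[prev] != steps[cur]:
            cut.add(prev)
            cut.add(cur)
    if not cut:
        return [path]
    pieces: list[list[Vertex]] = []
    piece = [path[0]]
    for i, v in enumerate(path[1:]):
        if i in cut:
            pieces.append(piece)
            piece = [v]
        else:
            piece.append(v)
    pieces.append(piece)
    return pieces


def _canonical(graph: ColouredOverlapGraph, path: list[Vertex]) -> list[Vertex]:
    """Pick one orientation of a unitig: colours non-decreasing if they
    decide, else lexicographically smallest first vertex."""
    mirror = [flip(v) for v in reversed(path)]
    direction: str | None = None
    for a, b in zip(path, path[1:]):
        step = _colour_step(graph.colour_of(a), graph.colour_of(b))
        if step in ("up", "down"):
            direction = step
            break
    if direction == "up":
        return path
    if direction == "down":
        return mirror
    return path if path[0] <= mirror[0] else mirror


def extract_unitigs(graph: ColouredOverlapGraph, d: int = 1) -> list[Unitig]:
    """Find all maximal guided unitigs; each reported once.

    Every vertex of the graph belongs to exactly one unitig path (its
    mirror belongs to the suppressed mirror path); isolated vertices
    yield single-read unitigs.
    """
    succ = _unitig_edges(graph, d)
    pred: dict[Vertex, Vertex] = {v: u for u, v in succ.items()}

    paths: list[list[Vertex]] = []
    visited: set[Vertex] = set()
    # path heads: no usable incoming edge
    for v in sorted(graph.g.nodes):
        if v in visited or v in pred:
            continue
        path = [v]
        visited.add(v)
        while path[-1] in succ and succ[path[-1]] not in visited:
            nxt = succ[path[-1]]
            path.append(nxt)
            visited.add(nxt)
        paths.append(path)
    # remaining vertices sit on cycles: canonicalize each cycle to the
    # lexicographically smallest rotation over both orientations, so a
    # cycle and its mirror reduce to one representative
    cycles: list[list[Vertex]] = []
    for v in sorted(graph.g.nodes):
        if v in visited:
            continue
        path = [v]
        visited.add(v)
        while succ[path[-1]] not in visited:
            nxt = succ[path[-1]]
            path.append(nxt)
            visited.add(nxt)
        mirror = [flip(x) for x in reversed(path)]
        for x in mirror:
            visited.add(x)
        n = len(path)
        best = min(
            tuple(p[k:] + p[:k]) for p in (path, mirror) for k in range(n)
        )
        cycles.append(list(best))

    seen: set[tuple[Vertex, ...]] = set()
    unitigs: list[Unitig] = []
    for cycle in cycles:
        key = tuple(cycle)
        if key in seen:
            continue
        seen.add(key)
        unitigs.append(
            Unitig(
                path=cycle,
                colour_list=[frozenset(graph.colour_of(v)) for v in cycle],
            )
        )
    for path in paths:
        for piece in _split_on_direction(graph, path):
            oriented = _canonical(graph, piece)
            key = tuple(oriented)
            mirror_key = tuple(flip(v) for v in reversed(oriented))
            if key in seen or mirror_key in seen:
                continue
            seen.add(key)
            unitigs.append(
                Unitig(
                    path=oriented,
                    colour_list=[
                        frozenset(graph.colour_of(v)) for v in oriented
                    ],
                )
            )
    return unitigs


# ---------------------------------------------------------------------
# Sequence spelling
# ---------------------------------------------------------------------

def _oriented_seq(reads: Mapping[str, str], v: Vertex) -> str:
    seq = reads[v[0]]
    return seq if v[1] == "+" else reverse_complement(seq)


def unitig_sequence(
    unitig: Unitig | Sequence[Vertex],
    reads: Mapping[str, str],
    graph: ColouredOverlapGraph | None = None,
    overlaps: Sequence[int] | None = None,
) -> str:
    """Spell a unitig: first read whole, then each next read minus its
    overlap prefix.  Total length is sum(read lengths) - sum(overlaps).

    Overlap lengths are taken from ``graph`` edges or given explicitly.
    """
    path = list(unitig.path if isinstance(unitig, Unitig) else unitig)
    if overlaps is None:
        if graph is None and len(path) > 1:
            raise ValueError("need a graph or explicit overlap lengths")
        overlaps = [
            graph.overlap_len(u, v) for u, v in zip(path, path[1:])
        ]
    parts = [_oriented_seq(reads, path[0])]
    for (u, v), ovl in zip(zip(path, path[1:]), overlaps):
        seq = _oriented_seq(reads, v)
        if ovl >= len(seq) or ovl >= len(reads[u[0]]):
            raise AssemblyError(
                f"overlap {ovl} not shorter than both reads {u[0]}, {v[0]}"
            )
        parts.append(seq[ovl:])
    return "".join(parts)


# ---------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------

def _colour_tag(unitig: Unitig) -> str:
    rng = unitig.colour_range()
    if rng is None:
        return ""
    return f"\tcl:Z:{rng[0].encode()},{rng[1].encode()}"


def write_unitigs(
    unitigs: Sequence[Unitig],
    fasta_path: str | Path | None = None,
    gfa_path: str | Path | None = None,
    reads: Mapping[str, str] | None = None,
    graph: ColouredOverlapGraph | None = None,
) -> None:
    """Write unitigs as FASTA and/or GFA with colour-range tags.

    FASTA headers carry ``LN:i:<len>`` and ``cl:Z:<min>,<max>``
    (integer-encoded colour range).  The GFA additionally stores the
    vertex path in a ``pa:Z:`` tag and the per-vertex colour sets in
    ``cv:Z:`` so paths round-trip exactly.
    """
    named = [(f"utg{i + 1:06d}", u) for i, u in enumerate(unitigs)]
    if fasta_path is not None:
        if reads is None:
            raise ValueError("FASTA output requires read sequences")
        with open(fasta_path, "w") as fh:
            for name, u in named:
                seq = u.sequence or unitig_sequence(u, reads, graph)
                fh.write(f">{name} LN:i:{len(seq)}{_colour_tag(u)}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
    if gfa_path is not None:
        lines = ["H\tVN:Z:1.0"]
        for name, u in named:
            if reads is not None:
                seq = u.sequence or unitig_sequence(u, reads, graph)
                body, ln = seq, len(seq)
            else:
                total = sum(
                    (graph.read_lengths[v[0]] if graph else 0) for v in u.path
                )
                ovl = (
                    sum(
                        graph.overlap_len(a, b)
                        for a, b in zip(u.path, u.path[1:])
                    )
                    if graph
                    else 0
                )
                body, ln = "*", total - ovl
            pa = ",".join(f"{r}{o}" for r, o in u.path)
            cv = ";".join(
                ",".join(str(c.encode()) for c in sorted(cs))
                for cs in u.colour_list
            )
            lines.append(
                f"S\t{name}\t{body}\tLN:i:{ln}{_colour_tag(u)}"
                f"\tpa:Z:{pa}\tcv:Z:{cv}"
            )
        with open(gfa_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def read_unitig_paths(gfa_path: str | Path) -> list[Unitig]:
    """Recover unitig paths (and colour lists) from a written unitig GFA."""
    out: list[Unitig] = []
    with open(gfa_path) as fh:
        for line in fh:
            if not line.startswith("S\t"):
                continue
            fields = line.rstrip("\n").split("\t")
            path: list[Vertex] = []
            colour_list: list[frozenset[Colour]] = []
            for tag in fields[3:]:
                if tag.startswith("pa:Z:"):
                    for tok in tag[5:].split(","):
                        path.append((tok[:-1], tok[-1]))
                elif tag.startswith("cv:Z:"):
                    for group in tag[5:].split(";"):
                        colour_list.append(
                            frozenset(
                                Colour.decode(int(t))
                                for t in group.split(",")
                                if t
                            )
                        )
            out.append(Unitig(path=path, colour_list=colour_list))
    return out


def n50(lengths: Sequence[int]) -> int:
    """N50 of a set of lengths: the length at which half the total is
    reached when summing from the longest down."""
    if not lengths:
        return 0
    total = sum(lengths)
    acc = 0
    for n in sorted(lengths, reverse=True):
        acc += n
        if acc * 2 >= total:
            return n
    return 0
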