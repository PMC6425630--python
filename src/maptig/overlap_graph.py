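"""The coloured overlap graph: bidirected read-overlap graph + colours.

Every retained read contributes two vertices, one per orientation, and
every suffix–prefix overlap contributes an edge together with its
reverse-complement mirror: edge (u, v) always coexists with (v̄, ū),
with the same overlap length.  Colour sets live per *read* — both
orientations of a read always carry the identical set.

Overlap classification follows the standard OLC triage of all-vs-all
PAF records: a record is either a containment (the contained read is
dropped with all its overlaps), an internal match (discarded — the
overlap does not reach both read ends, so it cannot be a true dovetail),
or a suffix–prefix overlap, which becomes an edge in the orientation the
overhangs dictate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .colouring import ReadColouring
from .linkage_map import Colour, colours_adjacent
from .paf import PafRecord, read_paf

logger = logging.getLogger(__name__)

Vertex = tuple[str, str]  # (read_id, '+' | '-')

DEFAULT_MIN_OVERLAP = 2000
DEFAULT_CONTAINMENT_FUZZ = 1000

_CIGAR_M = re.compile(r"^(\d+)M$")


class GFAFormatError(ValueError):
    """Raised for GFA features outside the supported S/L + <n>M subset."""


def flip(v: Vertex) -> Vertex:
    return (v[0], "-" if v[1] == "+" else "+")


def colour_sets_consistent(
    a: frozenset[Colour] | set[Colour],
    b: frozenset[Colour] | set[Colour],
    d: int,
) -> bool:
    """True iff some colour pair from a x b is within distance ``d``.

    Empty sets are vacuously consistent: an uncoloured read carries no
    evidence either way.
    """
    if not a or not b:
        return True
    by_chrom: dict[int, list[int]] = {}
    for c in a:
        by_chrom.setdefault(c.chromosome_index, []).append(c.ordinal)
    for c in b:
        ords = by_chrom.get(c.chromosome_index)
        if ords is None:
            continue
        for o in ords:
            if abs(o - c.ordinal) <= d:
                return True
    return False


@dataclass
class ColouredOverlapGraph:
    """Bidirected overlap graph with per-read colour sets.

    Backed by a :class:`networkx.DiGraph` whose nodes are
    ``(read_id, orientation)`` pairs and whose edges carry
    ``overlap_len`` (bp shared between source suffix and target prefix).
    """

    g: nx.DiGraph = field(default_factory=nx.DiGraph)
    read_lengths: dict[str, int] = field(default_factory=dict)
    colours: dict[str, set[Colour]] = field(default_factory=dict)
    #: read ids whose colours came from graph propagation, not mappings
    propagated: set[str] = field(default_factory=set)

    # -- construction ---------------------------------------------------
    def add_read(self, read_id: str, length: int) -> None:
        self.read_lengths[read_id] = length
        self.g.add_node((read_id, "+"))
        self.g.add_node((read_id, "-"))

    def add_edge(self, u: Vertex, v: Vertex, overlap_len: int) -> None:
        """Add (u, v) and its mirror (v̄, ū) with the same overlap."""
        if overlap_len <= 0:
            raise ValueError("overlap_len must be positive")
        self.g.add_edge(u, v, overlap_len=overlap_len)
        self.g.add_edge(flip(v), flip(u), overlap_len=overlap_len)

    def remove_edge(self, u: Vertex, v: Vertex) -> None:
        self.g.remove_edge(u, v)
        mu, mv = flip(v), flip(u)
        if (mu, mv) != (u, v) and self.g.has_edge(mu, mv):
            self.g.remove_edge(mu, mv)

    def remove_read(self, read_id: str) -> None:
        for orient in "+-":
            if self.g.has_node((read_id, orient)):
                self.g.remove_node((read_id, orient))
        self.read_lengths.pop(read_id, None)
        self.colours.pop(read_id, None)
        self.propagated.discard(read_id)

    # -- queries --------------------------------------------------------
    @property
    def reads(self) -> list[str]:
        return sorted(self.read_lengths)

    def vertices(self) -> list[Vertex]:
        return sorted(self.g.nodes)

    def edges(self) -> Iterator[tuple[Vertex, Vertex, int]]:
        for u, v, data in self.g.edges(data=True):
            yield u, v, data["overlap_len"]

    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def edge_pairs(self) -> list[tuple[Vertex, Vertex, int]]:
        """One representative per mirror pair, deterministically chosen."""
        out = []
        for u, v, ovl in self.edges():
            if (u, v) <= (flip(v), flip(u)):
                out.append((u, v, ovl))
        return sorted(out)

    def overlap_len(self, u: Vertex, v: Vertex) -> int:
        return self.g.edges[u, v]["overlap_len"]

    def colour_of(self, v: Vertex | str) -> set[Colour]:
        read_id = v if isinstance(v, str) else v[0]
        return self.colours.get(read_id, set())

    def set_colours(self, read_id: str, colours: Iterable[Colour]) -> None:
        self.colours[read_id] = set(colours)

    def check_mirror_symmetry(self) -> None:
        """Assert the bidirected invariant; raises AssertionError if broken."""
        for u, v, ovl in self.edges():
            mu, mv = flip(v), flip(u)
            assert self.g.has_edge(mu, mv), f"missing mirror of {u}->{v}"
            assert self.g.edges[mu, mv]["overlap_len"] == ovl, (
                f"mirror of {u}->{v} has different overlap length"
            )

    def copy(self) -> "ColouredOverlapGraph":
        return ColouredOverlapGraph(
            g=self.g.copy(),
            read_lengths=dict(self.read_lengths),
            colours={r: set(cs) for r, cs in self.colours.items()},
            propagated=set(self.propagated),
        )


# ---------------------------------------------------------------------
# Overlap classification (all-vs-all PAF -> graph)
# ---------------------------------------------------------------------

def _classify(
    rec: PafRecord, fuzz: int, min_overlap: int
) -> tuple[str, Vertex | None, Vertex | None, int]:
    """Triage one all-vs-all record.

    Returns (kind, u, v, overlap_len) with kind in {"edge",
    "query_contained", "target_contained", "internal", "short", "self"}.
    """
    if rec.query_name == rec.target_name:
        return ("self", None, None, 0)
    span = min(rec.query_end - rec.query_start, rec.target_end - rec.target_start)
    if span < min_overlap:
        return ("short", None, None, 0)

    q5 = rec.query_start
    q3 = rec.query_len - rec.query_end
    if rec.strand == "+":
        t5 = rec.target_start
        t3 = rec.target_len - rec.target_end
    else:  # orient the target so the overlap runs the same way as the query
        t5 = rec.target_len - rec.target_end
        t3 = rec.target_start

    # the unaligned overhangs inside the overlap region must be small,
    # otherwise the "overlap" does not reach the read ends (internal match)
    overhang = min(q5, t5) + min(q3, t3)
    if overhang > min(fuzz, int(0.8 * span)):
        return ("internal", None, None, 0)

    if q5 <= t5 and q3 <= t3:
        if q5 == t5 and q3 == t3 and rec.query_len > rec.target_len:
            return ("target_contained", None, None, 0)
        return ("query_contained", None, None, 0)
    if q5 >= t5 and q3 >= t3:
        return ("target_contained", None, None, 0)

    t_orient = "+" if rec.strand == "+" else "-"
    # clamp so every edge can be spelled: an overlap must stay strictly
    # shorter than both reads even under indel-driven length drift
    cap = min(rec.query_len, rec.target_len) - 1
    if q5 > t5:
        # suffix of query overlaps prefix of (oriented) target
        if rec.strand == "+":
            ovl = rec.target_end
        else:
            ovl = rec.target_len - rec.target_start
        ovl = min(ovl, cap)
        return ("edge", (rec.query_name, "+"), (rec.target_name, t_orient), ovl)
    # suffix of (oriented) target overlaps prefix of query
    ovl = min(rec.query_end, cap)
    return ("edge", (rec.target_name, t_orient), (rec.query_name, "+"), ovl)


def build_graph_from_paf(
    overlaps: str | Path | Iterable[PafRecord],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_read_len: int = 0,
    containment_fuzz: int = DEFAULT_CONTAINMENT_FUZZ,
) -> ColouredOverlapGraph:
    """Build an (uncoloured) overlap graph from all-vs-all PAF overlaps.

    Contained reads are identified first and removed together with all
    their overlaps, before any edge is added; internal matches,
    self-overlaps and overlaps spanning < ``min_overlap`` bp are
    discarded.  Reads shorter than ``min_read_len`` are dropped outright.
    """
    if isinstance(overlaps, (str, Path)):
        records = list(read_paf(overlaps))
    else:
        records = list(overlaps)

    lengths: dict[str, int] = {}
    for rec in records:
        lengths[rec.query_name] = rec.query_len
        lengths[rec.target_name] = rec.target_len

    dropped = {r for r, n in lengths.items() if n < min_read_len}
    classified = []
    for rec in records:
        kind, u, v, ovl = _classify(rec, containment_fuzz, min_overlap)
        if kind == "query_contained":
            dropped.add(rec.query_name)
        elif kind == "target_contained":
            dropped.add(rec.target_name)
        elif kind == "edge":
            classified.append((u, v, ovl))

    graph = ColouredOverlapGraph()
    for read_id, length in lengths.items():
        if read_id not in dropped:
            graph.add_read(read_id, length)
    for u, v, ovl in classified:
        if u[0] in dropped or v[0] in dropped:
            continue
        if graph.g.has_edge(u, v):
            continue  # duplicate record for the same pair
        graph.add_edge(u, v, ovl)
    return graph


# ---------------------------------------------------------------------
# GFA 1.0 round trip
# ---------------------------------------------------------------------

def write_gfa(
    graph: ColouredOverlapGraph,
    path: str | Path,
    sequences: dict[str, str] | None = None,
) -> None:
    """Write GFA 1.0 with one S line per read and one L line per mirror pair.

    Colours are carried on S lines as a ``cl:Z:`` tag of comma-separated
    integer-encoded colours.  Output is canonicalized (sorted S lines,
    then sorted L lines) so identical graphs serialize identically.
    """
    lines = ["H\tVN:Z:1.0"]
    for read_id in graph.reads:
        seq = sequences.get(read_id, "*") if sequences else "*"
        s = f"S\t{read_id}\t{seq}\tLN:i:{graph.read_lengths[read_id]}"
        colours = graph.colours.get(read_id)
        if colours:
            s += "\tcl:Z:" + ",".join(str(c.encode()) for c in sorted(colours))
        lines.append(s)
    for u, v, ovl in graph.edge_pairs():
        lines.append(f"L\t{u[0]}\t{u[1]}\t{v[0]}\t{v[1]}\t{ovl}M")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_gfa(path: str | Path) -> ColouredOverlapGraph:
    """Load a GFA 1.0 graph (S and L lines; overlaps must be ``<n>M``)."""
    graph = ColouredOverlapGraph()
    links: list[tuple[Vertex, Vertex, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line[0] in "#H":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                read_id, seq = fields[1], fields[2]
                length = None
                colours: set[Colour] = set()
                for tag in fields[3:]:
                    if tag.startswith("LN:i:"):
                        length = int(tag[5:])
                    elif tag.startswith("cl:Z:"):
                        colours = {
                            Colour.decode(int(tok))
                            for tok in tag[5:].split(",")
                            if tok
                        }
                if length is None:
                    if seq == "*":
                        raise GFAFormatError(
                            f"{path}:{lineno}: S line needs a sequence or LN tag"
                        )
                    length = len(seq)
                graph.add_read(read_id, length)
                if colours:
                    graph.set_colours(read_id, colours)
            elif fields[0] == "L":
                if len(fields) < 6:
                    raise GFAFormatError(
                        f"{path}:{lineno}: L line has {len(fields)} fields"
                    )
                m = _CIGAR_M.match(fields[5])
                if not m:
                    raise GFAFormatError(
                        f"{path}:{lineno}: unsupported overlap CIGAR "
                        f"{fields[5]!r} (only <n>M is supported)"
                    )
                links.append(
                    (
                        (fields[1], fields[2]),
                        (fields[3], fields[4]),
                        int(m.group(1)),
                    )
                )
    for u, v, ovl in links:
        for read_id, _ in (u, v):
            if read_id not in graph.read_lengths:
                raise GFAFormatError(
                    f"{path}: L line references unknown segment {read_id!r}"
                )
        graph.add_edge(u, v, ovl)
    return graph


# ---------------------------------------------------------------------
# Colours on the graph
# ---------------------------------------------------------------------

def attach_colours(
    graph: ColouredOverlapGraph, colouring: ReadColouring
) -> ColouredOverlapGraph:
    """Attach a read colouring to the graph (both orientations per read).

    Colouring entries for reads not present in the graph (e.g. dropped
    as contained) are ignored; the count of ignored entries is logged.
    """
    ignored = 0
    for read_id, colours in colouring.colours.items():
        if read_id in graph.read_lengths:
            graph.set_colours(read_id, colours)
        else:
            ignored += 1
    if ignored:
        logger.info("%d colouring entries had no read in the graph", ignored)
    return graph


def colour_consistent_degrees(
    graph: ColouredOverlapGraph, v: Vertex, d: int = 1
) -> tuple[int, int]:
    """(indegree, outdegree) counting only colour-consistent neighbours.

    A neighbour is consistent when it has at least one colour equal or
    adjacent (within distance ``max(1, d)``) to a colour of ``v``;
    vertices with empty colour sets are always consistent — an absent
    colouring is no evidence of a wrong join.
    """
    dist = max(1, d)
    cv = graph.colour_of(v)
    indeg = sum(
        1
        for u in graph.g.predecessors(v)
        if colour_sets_consistent(cv, graph.colour_of(u), dist)
    )
    outdeg = sum(
        1
        for w in graph.g.successors(v)
        if colour_sets_consistent(cv, graph.colour_of(w), dist)
    )
    return indeg, outdeg
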