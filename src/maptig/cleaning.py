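"""Graph cleaning: colour propagation, conflict removal, edge deletion.

This is the guided step of the pipeline.  Reads that received no colour
from their mappings are coloured from nearby coloured reads in the
overlap graph (bounded breadth-first search).  Reads whose propagated
colours skip part of the map order, or mix chromosomes, carry no usable
position signal and are removed.  Finally every edge joining two reads
whose colour sets share no pair of colours within distance ``d`` in the
map order is deleted — such an edge can never sit on a path whose
colours advance consecutively along a chromosome, so it is either
spurious or unusable.  A minimal topological simplification (transitive
reduction and tip clipping, the standard OLC layout steps) can follow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .linkage_map import Colour
from .overlap_graph import (
    ColouredOverlapGraph,
    Vertex,
    colour_sets_consistent,
    flip,
)

DEFAULT_DISTANCE = 1
DEFAULT_DEPTH_LIMIT = 10
DEFAULT_CONFLICT_GAP = 2
DEFAULT_TRANSITIVE_FUZZ = 1000
DEFAULT_MAX_TIP_LEN = 4


@dataclass
class CleanConfig:
    """Tunables of the cleaning step.

    ``d`` is the colour distance within which two colours still count as
    compatible (bins in noisy maps can be locally shuffled, so ``d=1``
    by default); ``depth_limit`` bounds the propagation search so distant
    colours are not over-approximated onto unmapped reads.
    """

    d: int = DEFAULT_DISTANCE
    depth_limit: int = DEFAULT_DEPTH_LIMIT
    simplify: bool = True

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("colour distance d must be >= 0")
        if self.depth_limit < 1:
            raise ValueError("depth_limit must be >= 1")


@dataclass
class CleanReport:
    """Counts of everything the cleaning pipeline did."""

    reads_propagated: int = 0
    conflict_reads_removed: int = 0
    inconsistent_edges_removed: int = 0  # mirror pairs
    transitive_edges_removed: int = 0  # mirror pairs
    tip_reads_removed: int = 0
    edges_before: int = 0  # mirror pairs
    edges_after: int = 0
    reads_before: int = 0
    reads_after: int = 0
    removed_by_chromosome: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            ("reads_propagated", self.reads_propagated),
            ("conflict_reads_removed", self.conflict_reads_removed),
            ("inconsistent_edges_removed", self.inconsistent_edges_removed),
            ("transitive_edges_removed", self.transitive_edges_removed),
            ("tip_reads_removed", self.tip_reads_removed),
            ("edges_before", self.edges_before),
            ("edges_after", self.edges_after),
            ("reads_before", self.reads_before),
            ("reads_after", self.reads_after),
        ]
        with open(path, "w") as fh:
            fh.write("#metric\tvalue\n")
            for k, v in rows:
                fh.write(f"{k}\t{v}\n")
            for chrom, n in sorted(self.removed_by_chromosome.items()):
                fh.write(f"inconsistent_edges_removed[{chrom}]\t{n}\n")


# ---------------------------------------------------------------------
# Colour propagation
# ---------------------------------------------------------------------

def propagate_colours(
    graph: ColouredOverlapGraph, depth_limit: int = DEFAULT_DEPTH_LIMIT
) -> ColouredOverlapGraph:
    """Colour uncoloured reads from nearby coloured reads in the graph.

    For each uncoloured read a breadth-first search runs over overlap
    edges in both directions, traversing only uncoloured reads, up to
    ``depth_limit`` edges; the read receives the union of the colour
    sets of every coloured read first reached.  The search is a single
    simultaneous pass seeded by the mapping-derived colouring only:
    reads coloured by a previous propagation are re-derived from the
    same seeds, never from each other, so the operation is idempotent
    and independent of read order.
    """
    # seed colouring = colours not themselves produced by propagation
    seeds = {
        r: cs
        for r, cs in graph.colours.items()
        if cs and r not in graph.propagated
    }

    adj: dict[str, set[str]] = {r: set() for r in graph.read_lengths}
    for u, v, _ in graph.edges():
        adj[u[0]].add(v[0])
        adj[v[0]].add(u[0])

    newly: dict[str, set[Colour]] = {}
    for read in graph.read_lengths:
        if read in seeds:
            continue
        gathered: set[Colour] = set()
        visited = {read}
        frontier = [read]
        depth = 0
        while frontier and depth < depth_limit:
            depth += 1
            nxt: list[str] = []
            for cur in frontier:
                for nb in adj[cur]:
                    if nb in visited:
                        continue
                    visited.add(nb)
                    if nb in seeds:
                        gathered |= seeds[nb]
                    else:
                        nxt.append(nb)
            frontier = nxt
        if gathered:
            newly[read] = gathered

    for read in graph.read_lengths:
        if read in seeds:
            continue
        if read in newly:
            graph.colours[read] = newly[read]
            graph.propagated.add(read)
        else:
            graph.colours.pop(read, None)
            graph.propagated.discard(read)
    return graph


# ---------------------------------------------------------------------
# Conflict removal
# ---------------------------------------------------------------------

def _has_colour_conflict(colours: set[Colour], max_gap: int) -> bool:
    """A colour set conflicts if it spans chromosomes or skips >= max_gap
    consecutive ordinals between its extremes on one chromosome."""
    if not colours:
        return False
    chroms = {c.chromosome_index for c in colours}
    if len(chroms) > 1:
        return True
    ordinals = sorted({c.ordinal for c in colours})
    for a, b in zip(ordinals, ordinals[1:]):
        if b - a - 1 >= max_gap:
            return True
    return False


def drop_conflicting_vertices(
    graph: ColouredOverlapGraph,
    max_gap: int = DEFAULT_CONFLICT_GAP,
    only_propagated: bool = True,
) -> tuple[ColouredOverlapGraph, int]:
    """Remove reads whose propagated colours skip genome or mix chromosomes.

    A propagated colour set with a run of >= ``max_gap`` missing
    ordinals between its minimum and maximum — or with colours from
    several chromosomes — means the read bridges distinct regions; its
    colouring cannot clean the graph, so the read is removed entirely
    (both orientations, all incident edges).  A single missing ordinal
    is tolerated: it is within the adjacency slack the cleaning distance
    itself allows for noisy maps.

    By default only reads coloured by propagation are examined; reads
    coloured directly from their mappings got all colours from one
    mapped locus and are trusted.
    """
    candidates = graph.propagated if only_propagated else set(graph.colours)
    to_drop = [
        r
        for r in sorted(candidates)
        if _has_colour_conflict(graph.colours.get(r, set()), max_gap)
    ]
    for r in to_drop:
        graph.remove_read(r)
    return graph, len(to_drop)


# ---------------------------------------------------------------------
# Inconsistent-edge removal (the core cleaning step)
# ---------------------------------------------------------------------

def remove_inconsistent_edges(
    graph: ColouredOverlapGraph, d: int = DEFAULT_DISTANCE
) -> tuple[ColouredOverlapGraph, CleanReport]:
    """Delete every edge whose endpoint colour sets share no colours
    within distance ``d``.

    Only edges with *both* endpoints coloured can be inconsistent:
    an empty colour set carries no evidence, and deleting on absence of
    evidence would disconnect legitimately unmapped reads.  Mirror edges
    are removed together, preserving the bidirected invariant.
    """
    report = CleanReport(edges_before=len(graph.edge_pairs()))
    by_chrom: dict[str, int] = {}
    for u, v, _ in graph.edge_pairs():
        cu, cv = graph.colour_of(u), graph.colour_of(v)
        if not cu or not cv:
            continue
        if not colour_sets_consistent(cu, cv, d):
            graph.remove_edge(u, v)
            report.inconsistent_edges_removed += 1
            chroms = {c.chromosome_index for c in cu} | {
                c.chromosome_index for c in cv
            }
            key = (
                f"chrom{chroms.pop()}" if len(chroms) == 1 else "cross-chromosome"
            )
            by_chrom[key] = by_chrom.get(key, 0) + 1
    report.removed_by_chromosome = by_chrom
    report.edges_after = len(graph.edge_pairs())
    return graph, report


# ---------------------------------------------------------------------
# Standard topological simplification
# ---------------------------------------------------------------------

def _reduce_transitive(
    graph: ColouredOverlapGraph, fuzz: int = DEFAULT_TRANSITIVE_FUZZ
) -> int:
    """Remove edges implied by a two-edge path with consistent layout.

    Edge (u, w) is transitive given (u, v) and (v, w) when placing w via
    v lands within ``fuzz`` bp of placing it via the direct edge:
    |ovl(u,w) + len(v) - ovl(u,v) - ovl(v,w)| <= fuzz.
    """
    marked: set[tuple[Vertex, Vertex]] = set()
    g = graph.g
    for u in g.nodes:
        succ_u = {w: g.edges[u, w]["overlap_len"] for w in g.successors(u)}
        for v, ovl_uv in succ_u.items():
            len_v = graph.read_lengths[v[0]]
            for w in g.successors(v):
                if w == u or w not in succ_u:
                    continue
                ovl_vw = g.edges[v, w]["overlap_len"]
                if abs(succ_u[w] + len_v - ovl_uv - ovl_vw) <= fuzz:
                    marked.add((u, w))
    removed = 0
    for u, w in sorted(marked):
        if graph.g.has_edge(u, w):
            graph.remove_edge(u, w)  # takes the mirror with it
            removed += 1
    return removed


def _clip_tips(
    graph: ColouredOverlapGraph, max_tip_len: int = DEFAULT_MAX_TIP_LEN
) -> int:
    """Remove dead-end branches of at most ``max_tip_len`` reads.

    A tip starts at a vertex with no incoming edge, follows unambiguous
    out-edges, and rejoins the graph at a vertex with other incoming
    edges within ``max_tip_len`` vertices.  A maximal path that never
    rejoins (an isolated chain) is not a tip and is kept.
    """
    g = graph.g
    tips: list[list[str]] = []
    for v in sorted(g.nodes):
        if g.in_degree(v) != 0:
            continue
        path = [v]
        cur = v
        is_tip = False
        while len(path) <= max_tip_len:
            if g.out_degree(cur) != 1:
                break
            nxt = next(iter(g.successors(cur)))
            if g.in_degree(nxt) > 1:
                is_tip = True
                break
            path.append(nxt)
            cur = nxt
        if is_tip and len(path) <= max_tip_len:
            tips.append([p[0] for p in path])
    removed_reads: set[str] = set()
    for path_reads in tips:
        removed_reads.update(path_reads)
    for r in sorted(removed_reads):
        graph.remove_read(r)
    return len(removed_reads)


def simplify_graph(
    graph: ColouredOverlapGraph,
    fuzz: int = DEFAULT_TRANSITIVE_FUZZ,
    max_tip_len: int = DEFAULT_MAX_TIP_LEN,
) -> tuple[ColouredOverlapGraph, int, int]:
    """Transitive reduction then tip clipping; returns (graph, n_trans, n_tip)."""
    n_trans = _reduce_transitive(graph, fuzz)
    n_tips = _clip_tips(graph, max_tip_len)
    return graph, n_trans, n_tips


# ---------------------------------------------------------------------
# Full cleaning pipeline
# ---------------------------------------------------------------------

def clean_graph(
    graph: ColouredOverlapGraph, config: CleanConfig | None = None
) -> tuple[ColouredOverlapGraph, CleanReport]:
    """Run propagate -> drop conflicts -> remove inconsistent edges ->
    simplify, in that order, and collect a report."""
    config = config or CleanConfig()
    report = CleanReport(
        reads_before=len(graph.read_lengths),
        edges_before=len(graph.edge_pairs()),
    )

    propagate_colours(graph, config.depth_limit)
    report.reads_propagated = len(graph.propagated)

    graph, n_conflicts = drop_conflicting_vertices(graph)
    report.conflict_reads_removed = n_conflicts

    graph, edge_report = remove_inconsistent_edges(graph, config.d)
    report.inconsistent_edges_removed = edge_report.inconsistent_edges_removed
    report.removed_by_chromosome = edge_report.removed_by_chromosome

    if config.simplify:
        graph, n_trans, n_tips = simplify_graph(graph)
        report.transitive_edges_removed = n_trans
        report.tip_reads_removed = n_tips

    report.reads_after = len(graph.read_lengths)
    report.edges_after = len(graph.edge_pairs())
    return graph, report
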