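"""Shared fixtures: hand-built graphs and a small simulated dataset."""

from __future__ import annotations

import numpy as np
import pytest

from maptig import (
    Colour,
    ColouredOverlapGraph,
    LinkageMap,
    simulate_genome_and_map,
    simulate_reads,
)
from maptig.simulate import emit_overlaps, emit_true_alignments


def make_graph(
    edges: list[tuple[str, str, str, str, int]],
    colours: dict[str, set[Colour]] | None = None,
    read_len: int = 10_000,
    extra_reads: list[str] = (),
) -> ColouredOverlapGraph:
    """Build a coloured graph from (read_a, orient_a, read_b, orient_b, ovl)."""
    graph = ColouredOverlapGraph()
    names = {a for a, *_ in edges} | {e[2] for e in edges} | set(extra_reads)
    for name in sorted(names):
        graph.add_read(name, read_len)
    for a, oa, b, ob, ovl in edges:
        graph.add_edge((a, oa), (b, ob), ovl)
    if colours:
        for read_id, cs in colours.items():
            graph.set_colours(read_id, cs)
    return graph


def chain_graph(
    n: int, colours: dict[str, set[Colour]] | None = None, ovl: int = 4000
) -> ColouredOverlapGraph:
    """A simple n-read forward chain r0 -> r1 -> ... (plus mirrors)."""
    edges = [(f"r{i}", "+", f"r{i+1}", "+", ovl) for i in range(n - 1)]
    return make_graph(edges, colours)


def random_coloured_graph(
    rng: np.random.Generator,
    n_reads: int = 3,
    p_edge: float = 0.5,
    n_colours: int = 5,
    n_chroms: int = 2,
    p_uncoloured: float = 0.2,
) -> ColouredOverlapGraph:
    """Random mirror-symmetric coloured graph for oracle comparisons."""
    graph = ColouredOverlapGraph()
    reads = [f"r{i}" for i in range(n_reads)]
    for r in reads:
        graph.add_read(r, 10_000)
    verts = [(r, o) for r in reads for o in "+-"]
    for i, u in enumerate(verts):
        for v in verts[i + 1 :]:
            if u[0] == v[0]:
                continue
            if rng.random() < p_edge:
                a, b = (v, u) if rng.random() < 0.5 else (u, v)
                if not graph.g.has_edge(a, b):
                    graph.add_edge(a, b, int(rng.integers(1000, 5000)))
    for r in reads:
        if rng.random() < p_uncoloured:
            continue
        k = int(rng.integers(1, 3))
        graph.set_colours(
            r,
            {
                Colour(int(rng.integers(0, n_chroms)), int(rng.integers(0, n_colours)))
                for _ in range(k)
            },
        )
    return graph


def correct_colours_from_truth(truth, lmap):
    """Colour every read with the bins its true interval covers."""
    from maptig.colouring import ReadColouring

    per_contig: dict[str, list[tuple[int, Colour]]] = {}
    for marker, colour in lmap.markers_with_colours():
        per_contig.setdefault(marker.contig, []).append((marker.pos, colour))
    for pairs in per_contig.values():
        pairs.sort()
    colouring = ReadColouring()
    for rec in truth.records.values():
        colours = {
            c
            for pos, c in per_contig.get(rec.chrom, [])
            if rec.start <= pos < rec.end
        }
        colouring.colours[rec.read_id] = colours
    return colouring


def is_rainbow(unitig) -> bool:
    """Colours confined to one chromosome, interval bounds non-decreasing
    along the path, and consecutive colour sets sharing or adjoining."""
    coloured = [cs for cs in unitig.colour_list if cs]
    if not coloured:
        return True
    chroms = {c.chromosome_index for cs in coloured for c in cs}
    if len(chroms) > 1:
        return False
    mins = [min(c.ordinal for c in cs) for cs in coloured]
    maxs = [max(c.ordinal for c in cs) for cs in coloured]
    if mins != sorted(mins) or maxs != sorted(maxs):
        return False
    for a, b in zip(coloured, coloured[1:]):
        gap = min(
            abs(ca.ordinal - cb.ordinal) for ca in a for cb in b
        )
        if gap > 1:
            return False
    return True


def theorem_graph(seed: int):
    """A correctly coloured truth-overlap graph with injected spurious
    edges: the setting in which cleaning must leave only rainbow unitigs."""
    from maptig import attach_colours, build_graph_from_paf

    genome, lmap = simulate_genome_and_map(n_chrom=1, chrom_len=60_000, seed=seed)
    reads, truth = simulate_reads(
        genome, coverage=20, mean_len=5000, len_sd=800, error_rate=0.0,
        seed=seed,
    )
    overlaps = emit_overlaps(
        truth, min_overlap=500, spurious_n=10, min_sep_bins=5, lmap=lmap,
        seed=seed,
    )
    graph = build_graph_from_paf(overlaps, min_overlap=500)
    attach_colours(graph, correct_colours_from_truth(truth, lmap))
    return graph, truth, lmap


@pytest.fixture(scope="session")
def small_sim():
    """A 2-chromosome simulation small enough for per-test reuse."""
    genome, lmap = simulate_genome_and_map(
        n_chrom=2, chrom_len=100_000, seed=3
    )
    reads, truth = simulate_reads(
        genome, coverage=20, mean_len=8000, len_sd=1500, error_rate=0.1, seed=3
    )
    return {
        "genome": genome,
        "lmap": lmap,
        "reads": reads,
        "truth": truth,
        "alignments": emit_true_alignments(truth, genome.lengths),
        "overlaps": emit_overlaps(
            truth, min_overlap=1000, spurious_n=20, min_sep_bins=5,
            lmap=lmap, seed=3,
        ),
    }


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free variant used where exact sequence identity matters."""
    genome, lmap = simulate_genome_and_map(
        n_chrom=1, chrom_len=80_000, seed=11
    )
    reads, truth = simulate_reads(
        genome, coverage=20, mean_len=6000, len_sd=1000, error_rate=0.0, seed=11
    )
    return {
        "genome": genome,
        "lmap": lmap,
        "reads": reads,
        "truth": truth,
        "alignments": emit_true_alignments(truth, genome.lengths),
        "overlaps": emit_overlaps(truth, min_overlap=1000),
    }
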