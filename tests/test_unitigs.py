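"""Guided unitig extraction, spelling, and output round trips."""

import itertools

import numpy as np
import pytest

from maptig import (
    attach_colours,
    build_graph_from_paf,
    extract_unitigs,
    remove_inconsistent_edges,
    unitig_sequence,
)
from maptig.linkage_map import Colour, colours_adjacent
from maptig.overlap_graph import flip
from maptig.unitigs import (
    AssemblyError,
    _colour_step,
    n50,
    read_unitig_paths,
    reverse_complement,
    write_unitigs,
)

from conftest import (
    chain_graph,
    correct_colours_from_truth,
    is_rainbow,
    make_graph,
    random_coloured_graph,
    theorem_graph,
)


class TestExtraction:
    def test_consistent_chain_is_one_unitig(self):
        graph = chain_graph(
            3,
            colours={
                "r0": {Colour(0, 1)},
                "r1": {Colour(0, 1)},
                "r2": {Colour(0, 2)},
            },
        )
        unitigs = extract_unitigs(graph, d=1)
        assert len(unitigs) == 1
        assert [v[0] for v in unitigs[0].path] == ["r0", "r1", "r2"]

    def test_distant_colours_split_uncleaned_chain(self):
        graph = chain_graph(
            2, colours={"r0": {Colour(0, 1)}, "r1": {Colour(0, 3)}}
        )
        unitigs = extract_unitigs(graph, d=1)
        assert len(unitigs) == 2
        assert all(len(u) == 1 for u in unitigs)

    def test_uncoloured_graph_degenerates_to_plain_unitigs(self):
        graph = chain_graph(5)
        unitigs = extract_unitigs(graph, d=1)
        assert len(unitigs) == 1
        assert len(unitigs[0]) == 5

    def test_branching_vertex_breaks_paths(self):
        graph = make_graph(
            [
                ("a", "+", "b", "+", 2000),
                ("a", "+", "c", "+", 2000),
            ]
        )
        unitigs = extract_unitigs(graph, d=1)
        # a branches: three single-read unitigs
        assert sorted(len(u) for u in unitigs) == [1, 1, 1]

    def test_each_read_reported_exactly_once(self, small_sim):
        graph = build_graph_from_paf(small_sim["overlaps"], min_overlap=1000)
        unitigs = extract_unitigs(graph, d=1)
        reported = [v[0] for u in unitigs for v in u.path]
        assert sorted(reported) == sorted(graph.read_lengths)

    def test_mirror_path_exists_but_not_reported(self, small_sim):
        graph = build_graph_from_paf(small_sim["overlaps"], min_overlap=1000)
        unitigs = extract_unitigs(graph, d=1)
        keys = {tuple(u.path) for u in unitigs}
        for u in unitigs:
            mirror = tuple(flip(v) for v in reversed(u.path))
            for a, b in zip(mirror, mirror[1:]):
                assert graph.g.has_edge(a, b)
            if mirror != tuple(u.path):
                assert mirror not in keys

    def test_isolated_cycle_reported_once(self):
        edges = [
            ("a", "+", "b", "+", 2000),
            ("b", "+", "c", "+", 2000),
            ("c", "+", "a", "+", 2000),
        ]
        graph = make_graph(edges)
        unitigs = extract_unitigs(graph, d=1)
        assert len(unitigs) == 1
        assert len(unitigs[0]) == 3


def oracle_unitigs(graph, d):
    """Exhaustive oracle: maximal colour-valid non-branching paths, built
    from the degree/adjacency definitions with singleton colour sets."""
    dist = max(1, d)

    def cons(a, b):
        return (
            not a
            or not b
            or any(
                colours_adjacent(x, y, dist)
                for x, y in itertools.product(a, b)
            )
        )

    def step(a, b):
        if not a or not b:
            return "none"
        (x,), (y,) = a, b
        if x.chromosome_index != y.chromosome_index:
            return "none"
        return "up" if y.ordinal > x.ordinal else (
            "down" if y.ordinal < x.ordinal else "flat"
        )

    nodes = list(graph.g.nodes)
    col = graph.colour_of
    cc_out = {
        v: sum(1 for w in graph.g.successors(v) if cons(col(v), col(w)))
        for v in nodes
    }
    cc_in = {
        v: sum(1 for u in graph.g.predecessors(v) if cons(col(v), col(u)))
        for v in nodes
    }
    usable = {
        (u, v)
        for u, v, _ in graph.edges()
        if cc_out[u] == 1 and cc_in[v] == 1 and cons(col(u), col(v))
    }
    succ = dict(usable)
    pred = {v: u for u, v in usable}

    # maximal paths: extend each vertex in both directions
    paths = set()
    for v in nodes:
        path = [v]
        while path[0] in pred and pred[path[0]] not in path:
            path.insert(0, pred[path[0]])
        while path[-1] in succ and succ[path[-1]] not in path:
            path.append(succ[path[-1]])
        paths.add(tuple(path))

    # split at both strict edges flanking a direction reversal
    def split(path):
        steps = [step(col(a), col(b)) for a, b in zip(path, path[1:])]
        strict = [i for i, s in enumerate(steps) if s in ("up", "down")]
        cut = set()
        for p, c in zip(strict, strict[1:]):
            if steps[p] != steps[c]:
                cut.update((p, c))
        pieces, piece = [], [path[0]]
        for i, v in enumerate(path[1:]):
            if i in cut:
                pieces.append(piece)
                piece = [v]
            else:
                piece.append(v)
        pieces.append(piece)
        return pieces

    out = set()
    cycles = set()
    for path in paths:
        if len(path) > 1 and pred.get(path[0]) == path[-1]:
            mirror = tuple(flip(v) for v in reversed(path))
            n = len(path)
            cycles.add(
                min(
                    tuple(p[k:] + p[:k])
                    for p in (tuple(path), mirror)
                    for k in range(n)
                )
            )
    paths = {p for p in paths if not (len(p) > 1 and pred.get(p[0]) == p[-1])}
    for path in paths:
        for piece in split(list(path)):
            mirror = [flip(v) for v in reversed(piece)]
            direction = None
            for a, b in zip(piece, piece[1:]):
                s = step(col(a), col(b))
                if s in ("up", "down"):
                    direction = s
                    break
            if direction == "down":
                piece = mirror
            elif direction is None and mirror[0] < piece[0]:
                piece = mirror
            out.add(tuple(piece))
    # drop mirrors that co-survived (palindromes keep one)
    dedup = set(cycles)
    for p in sorted(out):
        if tuple(flip(v) for v in reversed(p)) not in dedup:
            dedup.add(p)
    return dedup


class TestExhaustiveOracle:
    @pytest.mark.parametrize("seed", range(30))
    def test_matches_enumeration_on_small_graphs(self, seed):
        rng = np.random.default_rng(1000 + seed)
        graph = random_coloured_graph(
            rng, n_reads=3, p_edge=0.5, n_colours=3, n_chroms=2,
            p_uncoloured=0.3,
        )
        # singleton colour sets keep the oracle's step function exact
        for r in list(graph.colours):
            cs = graph.colours[r]
            if len(cs) > 1:
                graph.colours[r] = {sorted(cs)[0]}
        for d in (0, 1, 2):
            got = {tuple(u.path) for u in extract_unitigs(graph, d)}
            assert got == oracle_unitigs(graph, d)


class TestSequences:
    def test_two_read_overlap_spelling(self):
        graph = make_graph([("a", "+", "b", "+", 4)], read_len=8)
        seq = unitig_sequence(
            [("a", "+"), ("b", "+")],
            {"a": "ACGTACGT", "b": "ACGTTTTT"},
            graph,
        )
        assert seq == "ACGTACGTTTTT"

    def test_single_read_path_is_the_read(self):
        assert unitig_sequence([("a", "+")], {"a": "ACGTACGT"}) == "ACGTACGT"

    def test_minus_orientation_reverse_complements(self):
        assert unitig_sequence([("a", "-")], {"a": "AACG"}) == "CGTT"

    def test_overlap_longer_than_read_rejected(self):
        graph = make_graph([("a", "+", "b", "+", 9)], read_len=8)
        with pytest.raises(AssemblyError):
            unitig_sequence(
                [("a", "+"), ("b", "+")],
                {"a": "ACGTACGT", "b": "ACGTTTTT"},
                graph,
            )

    def test_error_free_chain_reconstructs_genome_segment(self, clean_sim):
        from maptig import simplify_graph

        graph = build_graph_from_paf(clean_sim["overlaps"], min_overlap=1000)
        graph, _, _ = simplify_graph(graph)
        unitigs = extract_unitigs(graph, d=1)
        longest = max(unitigs, key=len)
        seq = unitig_sequence(longest, clean_sim["reads"], graph)
        chrom_seq = clean_sim["genome"].sequences["chr0"]
        assert seq in chrom_seq or reverse_complement(seq) in chrom_seq
        assert len(seq) > 50_000  # most of the 80 kb chromosome

    def test_length_conservation(self, clean_sim):
        from maptig import simplify_graph

        graph = build_graph_from_paf(clean_sim["overlaps"], min_overlap=1000)
        graph, _, _ = simplify_graph(graph)
        for unitig in extract_unitigs(graph, d=1):
            seq = unitig_sequence(unitig, clean_sim["reads"], graph)
            expected = sum(
                graph.read_lengths[v[0]] for v in unitig.path
            ) - sum(
                graph.overlap_len(a, b)
                for a, b in zip(unitig.path, unitig.path[1:])
            )
            assert len(seq) == expected


class TestOutput:
    def test_fasta_and_gfa_round_trip(self, tmp_path):
        graph = chain_graph(
            3,
            colours={
                "r0": {Colour(0, 3)},
                "r1": {Colour(0, 4)},
                "r2": {Colour(0, 7)},
            },
            ovl=4,
        )
        reads = {"r0": "ACGTACGTAC", "r1": "GTACGGGTTT", "r2": "TTTTAACCGG"}
        for r in reads:
            graph.read_lengths[r] = 10
        unitigs = extract_unitigs(graph, d=5)
        fasta, gfa = tmp_path / "u.fa", tmp_path / "u.gfa"
        write_unitigs(unitigs, fasta, gfa, reads, graph)
        text = fasta.read_text()
        assert text.startswith(">utg000001 LN:i:")
        assert "cl:Z:3,7" in text
        reloaded = read_unitig_paths(gfa)
        assert [u.path for u in reloaded] == [u.path for u in unitigs]
        assert [u.colour_list for u in reloaded] == [
            u.colour_list for u in unitigs
        ]

    def test_empty_unitig_list_writes_empty_fasta(self, tmp_path):
        fasta = tmp_path / "u.fa"
        write_unitigs([], fasta, None, reads={})
        assert fasta.read_text() == ""

    def test_n50(self):
        assert n50([]) == 0
        assert n50([10]) == 10
        assert n50([1, 1, 8]) == 8
        assert n50([5, 5, 5, 5]) == 5


class TestRainbowProperty:
    @pytest.mark.parametrize("seed", range(5))
    def test_cleaned_truth_graphs_yield_rainbow_unitigs(self, seed):
        from maptig import clean_graph

        graph, truth, lmap = theorem_graph(seed)
        graph, _ = clean_graph(graph)
        unitigs = extract_unitigs(graph, d=1)
        assert any(len(u) > 3 for u in unitigs)  # non-trivial paths exist
        for unitig in unitigs:
            assert is_rainbow(unitig), unitig.path
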