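"""Simulator truth-consistency, densities, determinism, and evaluation."""

import numpy as np
import pytest

from maptig.evaluate import (
    EvaluationError,
    acceptable_colour_range,
    acceptable_colour_ranges,
    edge_is_genomic,
    evaluate_colouring,
    evaluate_edges,
)
from maptig.linkage_map import Colour, validate_map
from maptig.overlap_graph import build_graph_from_paf
from maptig.simulate import (
    SimTruth,
    TruthRecord,
    emit_overlaps,
    emit_true_alignments,
    simulate_genome_and_map,
    simulate_reads,
)
from maptig.unitigs import reverse_complement

from conftest import correct_colours_from_truth


class TestGenomeAndMap:
    def test_deterministic_for_fixed_seed(self):
        g1, m1 = simulate_genome_and_map(2, 50_000, seed=9)
        g2, m2 = simulate_genome_and_map(2, 50_000, seed=9)
        assert g1.sequences == g2.sequences
        assert m1.markers == m2.markers and m1.bins == m2.bins
        g3, _ = simulate_genome_and_map(2, 50_000, seed=10)
        assert g3.sequences != g1.sequences

    def test_marker_and_bin_densities(self):
        _, lmap = simulate_genome_and_map(1, 200_000, seed=4)
        marker_density = len(lmap.markers) / 200_000
        bin_density = len(lmap.bins) / 200_000
        assert marker_density == pytest.approx(0.008, rel=0.01)
        assert 0.001 < bin_density < 0.003

    def test_bins_separated_by_spacing(self):
        _, lmap = simulate_genome_and_map(1, 100_000, seed=4, bin_spacing=200)
        first_marker = {}
        for m in lmap.markers:
            first_marker.setdefault(m.bin_ref, m.pos)
        by_bin = sorted(
            first_marker.items(), key=lambda kv: lmap.colour_of_bin(kv[0])
        )
        for (_, p1), (_, p2) in zip(by_bin, by_bin[1:]):
            assert p2 - p1 >= 200

    def test_map_is_structurally_valid(self):
        genome, lmap = simulate_genome_and_map(2, 50_000, seed=4)
        assert validate_map(lmap, genome.lengths) == []

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            simulate_genome_and_map(1, 50, marker_density=0.001)
        with pytest.raises(ValueError):
            simulate_genome_and_map(1, 50_000, bin_spacing=0)


class TestReads:
    def test_read_count_matches_coverage(self):
        genome, _ = simulate_genome_and_map(1, 200_000, seed=5)
        reads, truth = simulate_reads(
            genome, coverage=20, mean_len=8000, len_sd=1000, seed=5
        )
        assert len(reads) == pytest.approx(20 * 200_000 / 8000, rel=0.1)
        assert len(truth) == len(reads)

    def test_error_free_reads_are_exact_substrings(self):
        genome, _ = simulate_genome_and_map(1, 60_000, seed=6)
        reads, truth = simulate_reads(
            genome, coverage=5, mean_len=5000, len_sd=500, error_rate=0.0,
            seed=6,
        )
        chrom = genome.sequences["chr0"]
        for read_id, seq in reads.items():
            rec = truth[read_id]
            expected = chrom[rec.start : rec.end]
            if rec.strand == "-":
                expected = reverse_complement(expected)
            assert seq == expected

    def test_errors_inflate_length_insertion_biased(self):
        genome, _ = simulate_genome_and_map(1, 100_000, seed=6)
        reads, truth = simulate_reads(
            genome, coverage=10, mean_len=8000, len_sd=500, error_rate=0.1,
            seed=6,
        )
        # net length change per base: +0.6*rate (ins) - 0.2*rate (del)
        ratios = [
            truth[r].read_len / (truth[r].end - truth[r].start) for r in reads
        ]
        assert np.mean(ratios) == pytest.approx(1.04, abs=0.01)

    def test_truth_tiles_genome_breadth(self):
        genome, _ = simulate_genome_and_map(1, 100_000, seed=8)
        _, truth = simulate_reads(
            genome, coverage=40, mean_len=5000, len_sd=500, seed=8
        )
        covered = np.zeros(100_000, dtype=bool)
        for rec in truth.records.values():
            covered[rec.start : rec.end] = True
        assert covered.mean() >= 0.99

    def test_truth_tsv_round_trip(self, tmp_path):
        genome, _ = simulate_genome_and_map(1, 50_000, seed=8)
        _, truth = simulate_reads(genome, coverage=3, mean_len=5000, seed=8)
        path = tmp_path / "truth.tsv"
        truth.write_tsv(path)
        assert SimTruth.read_tsv(path).records == truth.records


def two_read_truth(gap=False):
    truth = SimTruth()
    truth.records["a"] = TruthRecord("a", "chr0", 0, 10_000, "+", 10_000)
    b_start = 12_000 if gap else 7000
    truth.records["b"] = TruthRecord(
        "b", "chr0", b_start, b_start + 10_000, "+", 10_000
    )
    return truth


class TestOverlaps:
    def test_true_overlap_span(self):
        records = emit_overlaps(two_read_truth(), min_overlap=2000)
        assert len(records) == 1
        rec = records[0]
        assert rec.n_matches == 3000  # 3 kb true overlap
        assert (rec.query_start, rec.query_end) == (7000, 10_000)
        assert (rec.target_start, rec.target_end) == (0, 3000)

    def test_disjoint_reads_produce_no_overlap(self):
        assert emit_overlaps(two_read_truth(gap=True), min_overlap=2000) == []

    def test_minus_strand_read_coordinates(self):
        truth = two_read_truth()
        truth.records["b"] = TruthRecord("b", "chr0", 7000, 17_000, "-", 10_000)
        rec = emit_overlaps(truth, min_overlap=2000)[0]
        assert rec.strand == "-"
        # overlap [7000,10000) sits at the END of b's forward sequence
        assert (rec.target_start, rec.target_end) == (7000, 10_000)

    def test_without_injection_all_records_truth_supported(self, small_sim):
        truth = small_sim["truth"]
        for rec in emit_overlaps(truth, min_overlap=1000):
            assert edge_is_genomic(rec.query_name, rec.target_name, truth)

    def test_injected_pairs_are_map_distant(self, small_sim):
        truth, lmap = small_sim["truth"], small_sim["lmap"]
        ranges = acceptable_colour_ranges(lmap, truth)
        genomic = emit_overlaps(truth, min_overlap=1000)
        with_spurious = emit_overlaps(
            truth, min_overlap=1000, spurious_n=20, min_sep_bins=5,
            lmap=lmap, seed=3,
        )
        injected = with_spurious[len(genomic):]
        assert len(injected) == 20
        for rec in injected:
            ra = ranges[rec.query_name]
            rb = ranges[rec.target_name]
            assert (
                ra.low.chromosome_index != rb.low.chromosome_index
                or rb.low.ordinal - ra.high.ordinal >= 5
                or ra.low.ordinal - rb.high.ordinal >= 5
            )

    def test_impossible_injection_raises(self):
        # two overlapping reads can never be 5 bins apart
        from maptig.linkage_map import Bin, LinkageMap, Marker

        lmap = LinkageMap(
            bins=[Bin("b0", "chr0", 0)],
            markers=[Marker("chr0", 5000, "b0")],
        )
        with pytest.raises(ValueError, match="no eligible"):
            emit_overlaps(
                two_read_truth(), min_overlap=2000, spurious_n=1,
                min_sep_bins=5, lmap=lmap, seed=0,
            )


class TestAcceptableRange:
    def setup_method(self):
        self.genome, self.lmap = simulate_genome_and_map(1, 100_000, seed=12)
        _, self.truth = simulate_reads(
            self.genome, coverage=10, mean_len=6000, len_sd=800, seed=12
        )

    def test_flanking_marker_rule_matches_linear_scan(self):
        markers = sorted(
            self.lmap.markers_with_colours(), key=lambda mc: mc[0].pos
        )
        for rec in self.truth.records.values():
            rng = acceptable_colour_range(rec.read_id, self.lmap, self.truth)
            before = [c for m, c in markers if m.pos <= rec.start]
            after = [c for m, c in markers if m.pos >= rec.end]
            assert rng.low == (before[-1] if before else markers[0][1])
            assert rng.high == (after[0] if after else markers[-1][1])

    def test_read_before_first_marker_clamps_to_first_bin(self):
        truth = SimTruth()
        first_pos = min(m.pos for m in self.lmap.markers)
        truth.records["x"] = TruthRecord(
            "x", "chr0", 0, max(1, first_pos), "+", max(1, first_pos)
        )
        rng = acceptable_colour_range("x", self.lmap, truth)
        assert rng.low == Colour(0, 0)

    def test_unknown_read_raises(self):
        with pytest.raises(EvaluationError):
            acceptable_colour_range("ghost", self.lmap, SimTruth())


class TestEvaluate:
    def test_truth_coloured_reads_all_inside(self, small_sim):
        colouring = correct_colours_from_truth(
            small_sim["truth"], small_sim["lmap"]
        )
        ev = evaluate_colouring(colouring, small_sim["lmap"], small_sim["truth"])
        assert ev.fully_inside + ev.uncoloured == ev.n_reads
        assert ev.fully_outside == 0 and ev.partial == 0

    def test_truth_only_graph_all_genomic(self, small_sim):
        graph = build_graph_from_paf(
            emit_overlaps(small_sim["truth"], min_overlap=1000),
            min_overlap=1000,
        )
        ev = evaluate_edges(graph, small_sim["truth"])
        assert ev.total > 0
        assert ev.spurious == 0

    def test_spurious_count_matches_reclassification(self, small_sim):
        graph = build_graph_from_paf(small_sim["overlaps"], min_overlap=1000)
        ev = evaluate_edges(graph, small_sim["truth"])
        recount = sum(
            0 if edge_is_genomic(u[0], v[0], small_sim["truth"]) else 1
            for u, v, _ in graph.edge_pairs()
        )
        assert ev.spurious == recount
        assert ev.spurious > 0  # the injected overlaps are present

    def test_graph_read_without_truth_raises(self):
        truth = two_read_truth()
        del truth.records["b"]
        graph = build_graph_from_paf(
            emit_overlaps(two_read_truth(), min_overlap=2000),
            min_overlap=2000,
        )
        with pytest.raises(EvaluationError):
            evaluate_edges(graph, truth)
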