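"""Truth-based evaluation of colourings and overlap graphs.

Two questions, answerable only on simulated data where every read's
genomic origin is known:

* **Colouring accuracy** — for each read, the markers flanking its true
  interval define an acceptable colour range (last marker at or before
  its start, first marker at or after its end); a read is *fully
  inside* when every colour it received lies within that range,
  *fully outside* when none does, *partial* otherwise, and
  *uncoloured* when it received no colour at all.

* **Edge support** — an edge of the overlap graph is *genomic* when its
  two reads' true intervals overlap by at least one base on the same
  chromosome, and *spurious* otherwise.  Counts can be taken at any
  pipeline stage, so the effect of each cleaning step is measurable.
"""

from __future__ import annotations

import json
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from .colouring import ReadColouring
from .linkage_map import Colour, LinkageMap
from .overlap_graph import ColouredOverlapGraph
from .simulate import SimTruth


class EvaluationError(ValueError):
    """Raised when a read under evaluation has no truth record."""


@dataclass(frozen=True)
class ColourRange:
    """Acceptable colour interval [low, high] for one read."""

    low: Colour
    high: Colour

    def contains(self, c: Colour) -> bool:
        return (
            c.chromosome_index == self.low.chromosome_index
            and self.low.ordinal <= c.ordinal <= self.high.ordinal
        )


def _marker_index(lmap: LinkageMap) -> dict[str, tuple[list[int], list[Colour]]]:
    """Per-contig sorted marker positions with their colours."""
    per_contig: dict[str, list[tuple[int, Colour]]] = {}
    for marker, colour in lmap.markers_with_colours():
        per_contig.setdefault(marker.contig, []).append((marker.pos, colour))
    out = {}
    for contig, pairs in per_contig.items():
        pairs.sort()
        out[contig] = ([p for p, _ in pairs], [c for _, c in pairs])
    return out


def acceptable_colour_range(
    read_id: str,
    lmap: LinkageMap,
    truth: SimTruth,
    _index: dict | None = None,
) -> ColourRange:
    """Range from the last marker at/before the read's true start to the
    first marker at/after its true end; chromosome ends clamp to the
    first/last bin of the chromosome."""
    if read_id not in truth:
        raise EvaluationError(f"no truth record for read {read_id!r}")
    rec = truth[read_id]
    index = _index if _index is not None else _marker_index(lmap)
    positions, colours = index[rec.chrom]

    i = bisect_right(positions, rec.start) - 1
    low = colours[i] if i >= 0 else colours[0]
    j = bisect_left(positions, rec.end)
    high = colours[j] if j < len(colours) else colours[-1]
    return ColourRange(low=low, high=high)


def acceptable_colour_ranges(
    lmap: LinkageMap, truth: SimTruth
) -> dict[str, ColourRange]:
    index = _marker_index(lmap)
    return {
        rid: acceptable_colour_range(rid, lmap, truth, index)
        for rid in truth.records
    }


# ---------------------------------------------------------------------
# Colouring evaluation
# ---------------------------------------------------------------------

@dataclass
class ColouringEval:
    n_reads: int = 0
    fully_inside: int = 0
    partial: int = 0
    fully_outside: int = 0
    uncoloured: int = 0

    @property
    def pct_inside(self) -> float:
        return 100.0 * self.fully_inside / self.n_reads if self.n_reads else 0.0

    @property
    def pct_outside(self) -> float:
        return 100.0 * self.fully_outside / self.n_reads if self.n_reads else 0.0


def evaluate_colouring(
    colouring: ReadColouring, lmap: LinkageMap, truth: SimTruth
) -> ColouringEval:
    """Classify every read in the colouring against its acceptable range."""
    index = _marker_index(lmap)
    ev = ColouringEval()
    for read_id, colours in colouring.colours.items():
        rng = acceptable_colour_range(read_id, lmap, truth, index)
        ev.n_reads += 1
        if not colours:
            ev.uncoloured += 1
            continue
        inside = sum(1 for c in colours if rng.contains(c))
        if inside == len(colours):
            ev.fully_inside += 1
        elif inside == 0:
            ev.fully_outside += 1
        else:
            ev.partial += 1
    return ev


# ---------------------------------------------------------------------
# Edge evaluation
# ---------------------------------------------------------------------

@dataclass
class EdgeEval:
    genomic: int = 0
    spurious: int = 0
    spurious_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.genomic + self.spurious

    @property
    def pct_genomic(self) -> float:
        return 100.0 * self.genomic / self.total if self.total else 0.0


def edge_is_genomic(a_read: str, b_read: str, truth: SimTruth) -> bool:
    """True iff the two reads' true intervals overlap (>= 1 bp, same
    chromosome)."""
    for r in (a_read, b_read):
        if r not in truth:
            raise EvaluationError(f"read {r!r} in graph has no truth record")
    a, b = truth[a_read], truth[b_read]
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def evaluate_edges(graph: ColouredOverlapGraph, truth: SimTruth) -> EdgeEval:
    """Classify every edge (one per mirror pair) as genomic or spurious."""
    ev = EdgeEval()
    for u, v, _ in graph.edge_pairs():
        if edge_is_genomic(u[0], v[0], truth):
            ev.genomic += 1
        else:
            ev.spurious += 1
            ev.spurious_pairs.append((u[0], v[0]))
    return ev


# ---------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------

def evaluate(
    colouring: ReadColouring | None,
    graph: ColouredOverlapGraph | None,
    lmap: LinkageMap,
    truth: SimTruth,
) -> dict:
    """Evaluation report covering whichever of colouring/graph is given."""
    report: dict = {}
    if colouring is not None:
        ce = evaluate_colouring(colouring, lmap, truth)
        report["colouring"] = {
            "n_reads": ce.n_reads,
            "fully_inside": ce.fully_inside,
            "fully_inside_pct": round(ce.pct_inside, 4),
            "partial": ce.partial,
            "fully_outside": ce.fully_outside,
            "fully_outside_pct": round(ce.pct_outside, 4),
            "uncoloured": ce.uncoloured,
        }
    if graph is not None:
        ee = evaluate_edges(graph, truth)
        report["edges"] = {
            "total": ee.total,
            "genomic": ee.genomic,
            "genomic_pct": round(ee.pct_genomic, 4),
            "spurious": ee.spurious,
        }
    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
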