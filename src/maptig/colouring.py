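"""Read colouring: from draft-assembly mappings to per-read colour sets.

Each long read is mapped to the draft assembly (by minimap2 or the
built-in simulator; PAF in either case).  For every read only its
longest mapping is kept — one read, one locus; ambiguity is handled
downstream by propagation and conflict removal, not here.  The kept
mapping is stretched into a naive linear "alignment" covering the whole
read, capped at ``cap`` bp per side: long-read error is dominated by
insertions, so the read is usually longer than the genomic segment it
covers and an uncapped stretch would overshoot.  The stretched
intervals go into a block index over the draft contigs; each linkage-map
marker is then looked up and every read whose interval contains the
marker position receives that marker's bin colour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .linkage_map import Colour, LinkageMap
from .paf import PafRecord, read_paf

logger = logging.getLogger(__name__)

#: A read-to-draft mapping record is a plain PAF record.
MappingRecord = PafRecord

DEFAULT_EXTENSION_CAP = 250
DEFAULT_BLOCK_SIZE = 10_000


@dataclass(frozen=True)
class ExtendedInterval:
    """A mapping stretched toward whole-read coverage, on the target."""

    target_id: str
    start: int
    end: int
    read_id: str


def select_longest_mappings(
    records: Sequence[MappingRecord],
) -> list[MappingRecord]:
    """Keep the single longest mapping (by read-coordinate span) of a read.

    Ties are broken by (target_name, target_start) lexicographic order,
    so the result is deterministic regardless of input order.  Empty
    input yields empty output.
    """
    if not records:
        return []
    best = min(
        records,
        key=lambda r: (
            -(r.query_end - r.query_start),
            r.target_name,
            r.target_start,
        ),
    )
    return [best]


def extend_mapping(
    rec: MappingRecord, cap: int = DEFAULT_EXTENSION_CAP
) -> ExtendedInterval:
    """Stretch a mapping's target interval to cover the unmapped read ends.

    The unmapped prefix and suffix lengths are measured in read
    coordinates, clipped to ``cap``, and applied to the strand-
    appropriate target side: on the ``-`` strand the read *prefix*
    continues past the target *end*.  The result is clamped to
    ``[0, target_len)`` and never shrinks the original interval.
    """
    prefix = min(rec.query_start, cap)
    suffix = min(rec.query_len - rec.query_end, cap)
    if rec.strand == "+":
        left, right = prefix, suffix
    else:
        left, right = suffix, prefix
    return ExtendedInterval(
        target_id=rec.target_name,
        start=max(0, rec.target_start - left),
        end=min(rec.target_len, rec.target_end + right),
        read_id=rec.query_name,
    )


@dataclass
class BlockIndex:
    """Fixed-width block index over draft contigs for point queries.

    Each contig is split into ``block_size``-bp blocks; every interval
    is registered in all blocks it overlaps.  A point query scans one
    block and filters to exact containment, so it returns precisely the
    reads whose extended interval contains the position — block size
    affects speed only, never the answer.
    """

    block_size: int
    _blocks: dict[str, dict[int, list[ExtendedInterval]]] = field(
        default_factory=dict
    )

    def add(self, iv: ExtendedInterval) -> None:
        contig = self._blocks.setdefault(iv.target_id, {})
        if iv.end <= iv.start:
            return
        first = iv.start // self.block_size
        last = (iv.end - 1) // self.block_size
        for b in range(first, last + 1):
            contig.setdefault(b, []).append(iv)

    def query(self, contig: str, pos: int) -> set[str]:
        """Read ids whose extended interval contains ``pos`` (half-open)."""
        blocks = self._blocks.get(contig)
        if blocks is None:
            return set()
        return {
            iv.read_id
            for iv in blocks.get(pos // self.block_size, ())
            if iv.start <= pos < iv.end
        }

    def has_contig(self, contig: str) -> bool:
        return contig in self._blocks


def build_block_index(
    intervals: Iterable[ExtendedInterval],
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> BlockIndex:
    if block_size <= 0:
        raise ValueError("block_size must be positive")
    index = BlockIndex(block_size=block_size)
    for iv in intervals:
        index.add(iv)
    return index


@dataclass
class ReadColouring:
    """Mapping read_id -> set of Colour; the colouring c before the graph.

    Colour sets may be empty: reads overlapping no marker stay
    uncoloured until propagation on the overlap graph.
    """

    colours: dict[str, set[Colour]] = field(default_factory=dict)
    skipped_markers: int = 0

    def get(self, read_id: str) -> set[Colour]:
        return self.colours.get(read_id, set())

    def __len__(self) -> int:
        return len(self.colours)


def colour_reads(index: BlockIndex, lmap: LinkageMap) -> ReadColouring:
    """Assign each read the colours of every marker its interval contains.

    Markers on contigs absent from the index are counted and skipped
    with a warning (the map may cover contigs no read mapped to).
    """
    colouring = ReadColouring()
    skipped = 0
    for marker, colour in lmap.markers_with_colours():
        if not index.has_contig(marker.contig):
            skipped += 1
            continue
        for read_id in index.query(marker.contig, marker.pos):
            colouring.colours.setdefault(read_id, set()).add(colour)
    if skipped:
        logger.warning(
            "%d markers on contigs absent from the mapping index were skipped",
            skipped,
        )
    colouring.skipped_markers = skipped
    return colouring


def colour_reads_from_records(
    records: Iterable[MappingRecord],
    lmap: LinkageMap,
    cap: int = DEFAULT_EXTENSION_CAP,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> ReadColouring:
    """Full colouring pipeline: longest mapping -> extend -> index -> colour."""
    by_read: dict[str, list[MappingRecord]] = {}
    for rec in records:
        by_read.setdefault(rec.query_name, []).append(rec)
    intervals = [
        extend_mapping(kept, cap)
        for recs in by_read.values()
        for kept in select_longest_mappings(recs)
    ]
    index = build_block_index(intervals, block_size)
    colouring = colour_reads(index, lmap)
    # reads that mapped but hit no marker still appear, with empty sets
    for read_id in by_read:
        colouring.colours.setdefault(read_id, set())
    return colouring


def colour_reads_from_paf(
    paf_path: str | Path,
    lmap: LinkageMap,
    cap: int = DEFAULT_EXTENSION_CAP,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> ReadColouring:
    """As :func:`colour_reads_from_records`, reading mappings from PAF."""
    return colour_reads_from_records(read_paf(paf_path), lmap, cap, block_size)


def write_colouring(colouring: ReadColouring, path: str | Path) -> None:
    """TSV ``read_id<TAB>c1,c2,...`` with integer-encoded colours."""
    with open(path, "w") as fh:
        for read_id in sorted(colouring.colours):
            encoded = ",".join(
                str(c.encode()) for c in sorted(colouring.colours[read_id])
            )
            fh.write(f"{read_id}\t{encoded}\n")


def read_colouring(path: str | Path) -> ReadColouring:
    colouring = ReadColouring()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            read_id, _, encoded = line.partition("\t")
            colours = {
                Colour.decode(int(tok))
                for tok in encoded.split(",")
                if tok
            }
            colouring.colours[read_id] = colours
    return colouring
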