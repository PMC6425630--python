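"""Linkage maps: markers, bins, and the colour order they induce.

A linkage map is a set of genetic markers localised on draft-assembly
contigs.  Markers are grouped into *bins* (groups of co-segregating
markers that share one map position), bins are assigned to chromosomes,
and within each chromosome the bins are totally ordered.  A bin's
position in that order is its *colour* — the unit of long-range
positional information every downstream stage consumes.

The on-disk format is a 4-column TSV: ``contig``, ``pos`` (1-based in
the file, 0-based in memory), ``chromosome``, ``bin_id``.  Lines
beginning with ``#`` are comments.  Bin ordinals are assigned by first
appearance within each chromosome, so the file itself is the order
authority.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple


#: Multiplier used to pack a Colour into a single integer for GFA/TSV
#: tags: ``chromosome_index * COLOUR_BASE + ordinal``.  Chosen large
#: enough that integer subtraction of encoded colours never makes two
#: chromosomes look adjacent for any realistic distance parameter.
COLOUR_BASE = 1_000_000


class Colour(NamedTuple):
    """A (chromosome, bin-ordinal) pair; the colour of a linkage-map bin.

    Colours are totally ordered within a chromosome by ordinal.  Colours
    on different chromosomes are never equal and never adjacent.
    """

    chromosome_index: int
    ordinal: int

    def encode(self) -> int:
        """Pack into a single integer (for ``cl:Z:`` tags and TSVs)."""
        return self.chromosome_index * COLOUR_BASE + self.ordinal

    @classmethod
    def decode(cls, value: int) -> "Colour":
        return cls(value // COLOUR_BASE, value % COLOUR_BASE)


def colours_adjacent(c1: Colour, c2: Colour, d: int) -> bool:
    """True iff ``c1`` and ``c2`` are within distance ``d`` in the map order.

    Two colours are adjacent when they lie on the same chromosome and
    their ordinals differ by at most ``d``.  Colours on different
    chromosomes are never adjacent, for any ``d``: each chromosome is an
    independent linear order.
    """
    return (
        c1.chromosome_index == c2.chromosome_index
        and abs(c1.ordinal - c2.ordinal) <= d
    )


@dataclass(frozen=True)
class Marker:
    """A marker localised on a draft contig, member of exactly one bin."""

    contig: str
    pos: int  # 0-based coordinate on the contig
    bin_ref: str


@dataclass(frozen=True)
class Bin:
    """A group of co-segregating markers with a single map position."""

    id: str
    chromosome: str
    ordinal: int  # 0-based rank within the chromosome


@dataclass
class Violation:
    """One invariant breach found by :func:`validate_map`."""

    contig: str
    pos: int
    rule: str
    message: str
    informational: bool = False


class LinkageMapError(ValueError):
    """Raised for malformed or inconsistent linkage-map input."""


@dataclass
class LinkageMap:
    """Validated linkage map: ordered bins per chromosome plus markers.

    ``chromosomes`` lists chromosome labels in file order; the index of
    a label in this list is the ``chromosome_index`` of its colours.
    """

    bins: list[Bin]
    markers: list[Marker]
    chromosomes: list[str] = field(default_factory=list)
    _bin_colour: dict[str, Colour] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            seen: list[str] = []
            for b in self.bins:
                if b.chromosome not in seen:
                    seen.append(b.chromosome)
            self.chromosomes = seen
        if not self._bin_colour:
            idx = {c: i for i, c in enumerate(self.chromosomes)}
            self._bin_colour = {
                b.id: Colour(idx[b.chromosome], b.ordinal) for b in self.bins
            }

    def colour_of_bin(self, bin_id: str) -> Colour:
        return self._bin_colour[bin_id]

    def chromosome_index(self, label: str) -> int:
        return self.chromosomes.index(label)

    def bins_by_chromosome(self) -> dict[str, list[Bin]]:
        out: dict[str, list[Bin]] = {c: [] for c in self.chromosomes}
        for b in self.bins:
            out[b.chromosome].append(b)
        for bs in out.values():
            bs.sort(key=lambda b: b.ordinal)
        return out

    def markers_with_colours(self) -> list[tuple[Marker, Colour]]:
        return [(m, self._bin_colour[m.bin_ref]) for m in self.markers]

    def n_bins(self, chromosome: str | None = None) -> int:
        if chromosome is None:
            return len(self.bins)
        return sum(1 for b in self.bins if b.chromosome == chromosome)


def load_linkage_map(path: str | Path) -> LinkageMap:
    """Parse and validate a 4-column linkage-map TSV.

    Columns are ``contig``, ``pos`` (1-based), ``chromosome``,
    ``bin_id``.  Positions are converted to 0-based.  Bin ordinals are
    assigned by first-appearance order within each chromosome.

    Raises
    ------
    LinkageMapError
        On a malformed line (named by line number), a bin_id appearing
        under two chromosomes, a duplicate (contig, pos) marker, or an
        empty file.
    """
    path = Path(path)
    markers: list[Marker] = []
    chrom_order: list[str] = []
    bin_chrom: dict[str, str] = {}
    bin_order: dict[str, list[str]] = {}
    seen_pos: set[tuple[str, int]] = set()

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise LinkageMapError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            contig, pos_s, chrom, bin_id = fields[:4]
            try:
                pos1 = int(pos_s)
            except ValueError:
                raise LinkageMapError(
                    f"{path}:{lineno}: position {pos_s!r} is not an integer"
                ) from None
            if pos1 < 1:
                raise LinkageMapError(
                    f"{path}:{lineno}: position must be >= 1 (1-based file)"
                )
            pos = pos1 - 1
            if (contig, pos) in seen_pos:
                raise LinkageMapError(
                    f"{path}:{lineno}: duplicate marker at ({contig}, {pos1})"
                )
            seen_pos.add((contig, pos))
            if bin_id in bin_chrom:
                if bin_chrom[bin_id] != chrom:
                    raise LinkageMapError(
                        f"{path}:{lineno}: bin {bin_id!r} assigned to both "
                        f"chromosome {bin_chrom[bin_id]!r} and {chrom!r}"
                    )
            else:
                bin_chrom[bin_id] = chrom
                if chrom not in bin_order:
                    bin_order[chrom] = []
                    chrom_order.append(chrom)
                bin_order[chrom].append(bin_id)
            markers.append(Marker(contig=contig, pos=pos, bin_ref=bin_id))

    if not markers:
        raise LinkageMapError(f"{path}: empty linkage map")

    bins = [
        Bin(id=bid, chromosome=chrom, ordinal=i)
        for chrom in chrom_order
        for i, bid in enumerate(bin_order[chrom])
    ]
    return LinkageMap(bins=bins, markers=markers, chromosomes=chrom_order)


def write_linkage_map(lmap: LinkageMap, path: str | Path) -> None:
    """Write a map back to the 4-column TSV (positions 1-based on disk).

    Markers are written grouped by (chromosome, bin ordinal) so that a
    reload reproduces the same ordinals: ``load_linkage_map`` after
    ``write_linkage_map`` is the identity on validated maps.
    """
    by_bin: dict[str, Bin] = {b.id: b for b in lmap.bins}
    idx = {c: i for i, c in enumerate(lmap.chromosomes)}
    ordered = sorted(
        range(len(lmap.markers)),
        key=lambda i: (
            idx[by_bin[lmap.markers[i].bin_ref].chromosome],
            by_bin[lmap.markers[i].bin_ref].ordinal,
            i,
        ),
    )
    with open(path, "w") as fh:
        fh.write("#contig\tpos\tchromosome\tbin_id\n")
        for i in ordered:
            m = lmap.markers[i]
            b = by_bin[m.bin_ref]
            fh.write(f"{m.contig}\t{m.pos + 1}\t{b.chromosome}\t{b.id}\n")


def validate_map(
    lmap: LinkageMap, draft_lengths: Mapping[str, int] | None = None
) -> list[Violation]:
    """Check every structural invariant; violations are data, not errors.

    Checks marker positions against contig lengths (when known), bin
    resolution, consecutive 0-based ordinals per chromosome, duplicate
    (contig, pos) markers, and — informationally — bins whose markers
    span multiple draft contigs (legal: draft contigs are unordered
    fragments, a bin may straddle a contig boundary).
    """
    violations: list[Violation] = []
    bin_ids = {b.id for b in lmap.bins}

    seen: dict[tuple[str, int], int] = {}
    bin_contigs: dict[str, set[str]] = {}
    for m in lmap.markers:
        if m.bin_ref not in bin_ids:
            violations.append(
                Violation(m.contig, m.pos, "unresolved-bin",
                          f"marker references unknown bin {m.bin_ref!r}")
            )
        if m.pos < 0:
            violations.append(
                Violation(m.contig, m.pos, "negative-position",
                          "marker position is negative")
            )
        if draft_lengths is not None and m.contig in draft_lengths:
            if m.pos >= draft_lengths[m.contig]:
                violations.append(
                    Violation(
                        m.contig, m.pos, "out-of-range",
                        f"marker at {m.pos} beyond contig length "
                        f"{draft_lengths[m.contig]}")
                )
        key = (m.contig, m.pos)
        seen[key] = seen.get(key, 0) + 1
        bin_contigs.setdefault(m.bin_ref, set()).add(m.contig)

    for (contig, pos), n in seen.items():
        if n > 1:
            violations.append(
                Violation(contig, pos, "duplicate-marker",
                          f"{n} markers share ({contig}, {pos})")
            )

    for chrom, bs in lmap.bins_by_chromosome().items():
        if not bs:
            violations.append(
                Violation("", -1, "empty-chromosome",
                          f"chromosome {chrom!r} has no bins")
            )
            continue
        ordinals = [b.ordinal for b in bs]
        if ordinals != list(range(len(ordinals))):
            violations.append(
                Violation("", -1, "non-consecutive-ordinals",
                          f"chromosome {chrom!r} ordinals {ordinals} are not "
                          f"0..{len(ordinals) - 1}")
            )

    for bid, contigs in bin_contigs.items():
        if len(contigs) > 1:
            violations.append(
                Violation(sorted(contigs)[0], -1, "multi-contig-bin",
                          f"bin {bid!r} has markers on {len(contigs)} contigs",
                          informational=True)
            )

    return violations


def write_violations(violations: Iterable[Violation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tpos\trule\tmessage\n")
        for v in violations:
            fh.write(f"{v.contig}\t{v.pos}\t{v.rule}\t{v.message}\n")
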