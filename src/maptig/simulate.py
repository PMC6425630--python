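"""Synthetic data with known truth: genome, linkage map, reads, overlaps.

The generator emulates the study conditions the pipeline is designed
for: a repeat-free multi-chromosome genome (uniform random bases), a
dense linkage map (markers placed uniformly at random, then grouped
into bins separated by at least a minimum spacing — default densities
around 0.008 markers/bp and 0.002 bins/bp), long reads of known origin
with an insertion-biased uniform error model, the true read-to-draft
alignments, and the true suffix–prefix overlaps, optionally with
injected spurious overlaps joining reads from distant parts of the map.

The simulated genome doubles as its own draft assembly: markers are
placed directly on the chromosome sequences.  This isolates the guided
cleaning from draft-assembly quality, which is a separate concern.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .linkage_map import Bin, LinkageMap, Marker
from .paf import PafRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_MARKER_DENSITY = 0.008
DEFAULT_BIN_SPACING = 200
DEFAULT_COVERAGE = 40.0
DEFAULT_MEAN_READ_LEN = 15_000
DEFAULT_READ_LEN_SD = 3_000
DEFAULT_ERROR_RATE = 0.10
#: insertion : deletion : substitution mix — insertions dominate long-read
#: error spectra, which is also why mapping extension is capped
ERROR_MIX = (0.6, 0.2, 0.2)


@dataclass
class SimGenome:
    """Per-chromosome uniform-random sequences; reproducible from seed."""

    sequences: dict[str, str]
    seed: int

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True)
class TruthRecord:
    """True origin of one simulated read."""

    read_id: str
    chrom: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    read_len: int


@dataclass
class SimTruth:
    """True genomic interval per simulated read (evaluator-only data)."""

    records: dict[str, TruthRecord] = field(default_factory=dict)

    def __getitem__(self, read_id: str) -> TruthRecord:
        return self.records[read_id]

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#read_id\tchrom\tstart\tend\tstrand\tread_len\n")
            for r in self.records.values():
                fh.write(
                    f"{r.read_id}\t{r.chrom}\t{r.start}\t{r.end}"
                    f"\t{r.strand}\t{r.read_len}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimTruth":
        truth = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                rid, chrom, s, e, strand, rl = line.rstrip("\n").split("\t")
                truth.records[rid] = TruthRecord(
                    rid, chrom, int(s), int(e), strand, int(rl)
                )
        return truth


# ---------------------------------------------------------------------
# Genome and linkage map
# ---------------------------------------------------------------------

def simulate_genome_and_map(
    n_chrom: int = 2,
    chrom_len: int = 1_000_000,
    marker_density: float = DEFAULT_MARKER_DENSITY,
    bin_spacing: int = DEFAULT_BIN_SPACING,
    seed: int = 0,
) -> tuple[SimGenome, LinkageMap]:
    """Random genome plus a dense simulated linkage map on it.

    Markers are placed uniformly at random on each chromosome;
    consecutive markers closer than ``bin_spacing`` bp share a bin, so
    bins are separated by at least ``bin_spacing`` bp.  At the default
    densities this yields roughly 0.008 markers/bp and 0.002 bins/bp.
    The genome serves directly as the draft assembly the map is called
    on: marker contigs are the chromosome names.
    """
    if marker_density * chrom_len < 1:
        raise ValueError("marker_density * chrom_len must be >= 1")
    if bin_spacing < 1:
        raise ValueError("bin_spacing must be >= 1")
    rng = np.random.default_rng(seed)

    sequences: dict[str, str] = {}
    markers: list[Marker] = []
    bins: list[Bin] = []
    chrom_names = [f"chr{i}" for i in range(n_chrom)]
    for chrom in chrom_names:
        codes = rng.integers(0, 4, size=chrom_len, dtype=np.uint8)
        sequences[chrom] = _BASES[codes].tobytes().decode()

        n_markers = int(round(marker_density * chrom_len))
        positions = np.sort(
            rng.choice(chrom_len, size=n_markers, replace=False)
        )
        ordinal = -1
        prev = None
        for pos in positions.tolist():
            if prev is None or pos - prev >= bin_spacing:
                ordinal += 1
                bins.append(
                    Bin(id=f"{chrom}_b{ordinal}", chromosome=chrom,
                        ordinal=ordinal)
                )
            markers.append(
                Marker(contig=chrom, pos=pos, bin_ref=f"{chrom}_b{ordinal}")
            )
            prev = pos

    genome = SimGenome(sequences=sequences, seed=seed)
    lmap = LinkageMap(bins=bins, markers=markers, chromosomes=chrom_names)
    return genome, lmap


# ---------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------

def _apply_errors(
    codes: np.ndarray, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Uniform i.i.d. per-base errors with an insertion-biased mix."""
    if error_rate <= 0:
        return codes
    n = codes.size
    err = rng.random(n) < error_rate
    kind = rng.random(n)  # only consulted where err is set
    ins = err & (kind < ERROR_MIX[0])
    dele = err & (kind >= ERROR_MIX[0]) & (kind < ERROR_MIX[0] + ERROR_MIX[1])
    sub = err & ~ins & ~dele

    out = codes.copy()
    if sub.any():
        out[sub] = (out[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    counts = np.ones(n, dtype=np.int64)
    counts[dele] = 0
    counts[ins] = 2
    expanded = np.repeat(out, counts)
    if ins.any():
        # the second copy of each duplicated base becomes a random insert
        ends = np.cumsum(counts)
        insert_at = ends[ins] - 1
        expanded[insert_at] = rng.integers(
            0, 4, size=insert_at.size, dtype=np.uint8
        )
    return expanded


def simulate_reads(
    genome: SimGenome,
    coverage: float = DEFAULT_COVERAGE,
    mean_len: int = DEFAULT_MEAN_READ_LEN,
    len_sd: int = DEFAULT_READ_LEN_SD,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
) -> tuple[dict[str, str], SimTruth]:
    """Sample reads uniformly over the genome with known origins.

    Start positions are uniform, lengths truncated-normal (clipped to
    [500, chromosome length]), strands fair coin.  Errors are i.i.d.
    per base at ``error_rate`` with an insertion : deletion :
    substitution mix of 6:2:2.  With ``error_rate=0`` every read is an
    exact substring of the genome or its reverse complement.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    lens = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    if mean_len >= lens.min():
        raise ValueError("mean read length must be below chromosome length")
    n_reads = int(round(coverage * genome.total_length / mean_len))

    chrom_idx = rng.choice(len(chroms), size=n_reads, p=lens / lens.sum())
    raw_lens = rng.normal(mean_len, len_sd, size=n_reads)
    arrays = {
        c: np.frombuffer(genome.sequences[c].encode(), dtype=np.uint8)
        for c in chroms
    }
    code_of = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i

    reads: dict[str, str] = {}
    truth = SimTruth()
    for i in range(n_reads):
        chrom = chroms[int(chrom_idx[i])]
        clen = len(genome.sequences[chrom])
        length = int(np.clip(raw_lens[i], 500, clen))
        start = int(rng.integers(0, clen - length + 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        codes = code_of[arrays[chrom][start:end]]
        if strand == "-":
            codes = (3 - codes)[::-1]  # reverse complement in code space
        codes = _apply_errors(codes, error_rate, rng)
        read_id = f"read{i:06d}"
        reads[read_id] = _BASES[codes].tobytes().decode()
        truth.records[read_id] = TruthRecord(
            read_id, chrom, start, end, strand, len(codes)
        )
    return reads, truth


# ---------------------------------------------------------------------
# True alignments and overlaps (PAF byproducts of the truth)
# ---------------------------------------------------------------------

def emit_true_alignments(
    truth: SimTruth, genome_lengths: dict[str, int]
) -> list[PafRecord]:
    """One whole-read PAF mapping per read, straight from the truth."""
    records = []
    for r in truth.records.values():
        span = r.end - r.start
        records.append(
            PafRecord(
                query_name=r.read_id,
                query_len=r.read_len,
                query_start=0,
                query_end=r.read_len,
                strand=r.strand,
                target_name=r.chrom,
                target_len=genome_lengths[r.chrom],
                target_start=r.start,
                target_end=r.end,
                n_matches=min(span, r.read_len),
                block_len=max(span, r.read_len),
                mapq=60,
            )
        )
    return records


def _to_read_coords(rec: TruthRecord, g1: int, g2: int) -> tuple[int, int]:
    """Project genomic subinterval [g1, g2) of a read's origin into the
    read's own (forward) coordinates, scaling for indel length drift."""
    span = rec.end - rec.start
    scale = rec.read_len / span
    if rec.strand == "+":
        a = int(round((g1 - rec.start) * scale))
        b = int(round((g2 - rec.start) * scale))
    else:
        a = int(round((rec.end - g2) * scale))
        b = int(round((rec.end - g1) * scale))
    a = max(0, min(rec.read_len - 1, a))
    b = max(a + 1, min(rec.read_len, b))
    return a, b


def _overlap_record(a: TruthRecord, b: TruthRecord, o1: int, o2: int) -> PafRecord:
    qs, qe = _to_read_coords(a, o1, o2)
    ts, te = _to_read_coords(b, o1, o2)
    return PafRecord(
        query_name=a.read_id,
        query_len=a.read_len,
        query_start=qs,
        query_end=qe,
        strand="+" if a.strand == b.strand else "-",
        target_name=b.read_id,
        target_len=b.read_len,
        target_start=ts,
        target_end=te,
        n_matches=o2 - o1,
        block_len=o2 - o1,
        mapq=255,
    )


def emit_overlaps(
    truth: SimTruth,
    min_overlap: int = 2000,
    spurious_n: int = 0,
    min_sep_bins: int = 5,
    lmap: LinkageMap | None = None,
    seed: int = 0,
) -> list[PafRecord]:
    """True suffix–prefix overlaps, plus optional injected spurious ones.

    A true overlap record is emitted for every read pair whose truth
    intervals overlap by at least ``min_overlap`` bp.  Spurious records
    join ``spurious_n`` read pairs whose acceptable colour ranges are at
    least ``min_sep_bins`` bin ordinals apart (or on different
    chromosomes); they are fabricated as clean dovetails (suffix of one
    read onto prefix of the other) so they survive overlap triage and
    must be caught by the colour cleaning.
    """
    recs = sorted(
        truth.records.values(), key=lambda r: (r.chrom, r.start, r.read_id)
    )
    out: list[PafRecord] = []
    for i, a in enumerate(recs):
        for j in range(i + 1, len(recs)):
            b = recs[j]
            if b.chrom != a.chrom or b.start >= a.end:
                break
            o1, o2 = b.start, min(a.end, b.end)
            if o2 - o1 >= min_overlap:
                out.append(_overlap_record(a, b, o1, o2))

    if spurious_n > 0:
        if lmap is None:
            raise ValueError("spurious injection needs the linkage map")
        from .evaluate import acceptable_colour_ranges

        ranges = acceptable_colour_ranges(lmap, truth)
        rng = np.random.default_rng(seed)
        # only join reads that survive containment triage: a spurious
        # overlap onto a read absent from the graph would test nothing
        contained: set[str] = set()
        for i, a in enumerate(recs):
            for j in range(i + 1, len(recs)):
                b = recs[j]
                if b.chrom != a.chrom or b.start >= a.end:
                    break
                if b.end <= a.end:
                    contained.add(b.read_id)
                elif b.start == a.start:
                    contained.add(a.read_id)
        ids = [r.read_id for r in recs if r.read_id not in contained]
        if len(ids) < 2:
            raise ValueError("not enough uncontained reads for injection")
        chosen: list[tuple[str, str]] = []
        attempts = 0
        while len(chosen) < spurious_n:
            attempts += 1
            if attempts > 1000 * max(1, spurious_n):
                raise ValueError(
                    "no eligible distant read pair for spurious injection"
                )
            i, j = rng.integers(0, len(ids), size=2)
            if i == j:
                continue
            la = truth.records[ids[int(i)]].read_len
            lb = truth.records[ids[int(j)]].read_len
            if min(la, lb) < min_overlap + 2000:
                continue  # too short to fabricate a surviving dovetail
            ra, rb = ranges[ids[int(i)]], ranges[ids[int(j)]]
            far = ra.low.chromosome_index != rb.low.chromosome_index or (
                rb.low.ordinal - ra.high.ordinal >= min_sep_bins
                or ra.low.ordinal - rb.high.ordinal >= min_sep_bins
            )
            if far:
                chosen.append((ids[int(i)], ids[int(j)]))
        for qa, qb in chosen:
            a, b = truth.records[qa], truth.records[qb]
            L = max(min_overlap, min(a.read_len, b.read_len) // 3)
            L = min(L, a.read_len - 1500, b.read_len - 1500)
            out.append(
                PafRecord(
                    query_name=qa,
                    query_len=a.read_len,
                    query_start=a.read_len - L,
                    query_end=a.read_len,
                    strand="+",
                    target_name=qb,
                    target_len=b.read_len,
                    target_start=0,
                    target_end=L,
                    n_matches=L,
                    block_len=L,
                    mapq=255,
                )
            )
    return out


# ---------------------------------------------------------------------
# FASTA / FASTQ output helpers
# ---------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
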