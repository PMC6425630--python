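"""Minimal PAF (pairwise mapping format) reading and writing.

Only the 12 mandatory columns are interpreted; trailing SAM-style tags
are preserved on read but ignored.  Coordinates are 0-based half-open,
as emitted by minimap2 and consumed by miniasm-style overlappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator


class PAFError(ValueError):
    """Raised for a malformed PAF line, naming the line number."""


@dataclass(frozen=True)
class PafRecord:
    query_name: str
    query_len: int
    query_start: int
    query_end: int
    strand: str  # '+' or '-'
    target_name: str
    target_len: int
    target_start: int
    target_end: int
    n_matches: int
    block_len: int
    mapq: int = 255

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.query_name, self.query_len, self.query_start,
                self.query_end, self.strand, self.target_name,
                self.target_len, self.target_start, self.target_end,
                self.n_matches, self.block_len, self.mapq,
            )
        )


def parse_paf_line(line: str, lineno: int = 0) -> PafRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise PAFError(
            f"line {lineno}: expected >=12 PAF columns, got {len(fields)}"
        )
    try:
        rec = PafRecord(
            query_name=fields[0],
            query_len=int(fields[1]),
            query_start=int(fields[2]),
            query_end=int(fields[3]),
            strand=fields[4],
            target_name=fields[5],
            target_len=int(fields[6]),
            target_start=int(fields[7]),
            target_end=int(fields[8]),
            n_matches=int(fields[9]),
            block_len=int(fields[10]),
            mapq=int(fields[11]),
        )
    except ValueError as exc:
        raise PAFError(f"line {lineno}: {exc}") from None
    if rec.strand not in "+-":
        raise PAFError(f"line {lineno}: strand must be + or -, got {rec.strand!r}")
    return rec


def read_paf(path: str | Path) -> Iterator[PafRecord]:
    """Yield records from a PAF file, skipping blank lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            yield parse_paf_line(line, lineno)


def write_paf(records, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")
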