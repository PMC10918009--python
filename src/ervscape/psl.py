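"""PSL alignment records: parsing, writing, and block accounting.

A PSL line describes one local alignment of a query (here: the proviral
consensus) against a target (a genome) as a set of gap-free blocks.  The
fields relevant to provirus profiling are ``match``/``mismatch`` (aligned
bases), ``q_gap_bases`` (consensus bases missing from the locus — deletions
relative to the provirus) and ``t_gap_bases`` (extra genomic bases inside the
locus — insertions into the provirus).

Internally all coordinates are 0-based half-open, the PSL convention.  For
minus-strand alignments the per-block query starts printed in a PSL file are
in reverse-complement coordinates; on read they are normalized to
plus-strand consensus coordinates, and on write converted back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

PSL_COLUMNS = 21


class PslParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentRecord:
    """One local alignment with PSL-like block and gap accounting."""

    q_name: str
    t_name: str
    strand: str
    match: int
    mismatch: int
    q_gap_count: int
    q_gap_bases: int
    t_gap_count: int
    t_gap_bases: int
    q_size: int
    q_start: int
    q_end: int
    t_size: int
    t_start: int
    t_end: int
    blocks: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)
    # blocks: (q_start, t_start, length), q in plus-strand consensus coords

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.match + self.mismatch != sum(b[2] for b in self.blocks):
            raise ValueError(
                f"match+mismatch ({self.match}+{self.mismatch}) != total block "
                f"length {sum(b[2] for b in self.blocks)}"
            )
        if self.q_end > self.q_size:
            raise ValueError(f"q_end {self.q_end} > query size {self.q_size}")
        prev_t = -1
        for _, ts, ln in self.blocks:
            if ts < prev_t:
                raise ValueError("blocks must ascend on the target axis")
            prev_t = ts + ln

    @property
    def aligned_bases(self) -> int:
        return self.match + self.mismatch

    def query_intervals(self) -> list[tuple[int, int]]:
        """Covered consensus intervals, 0-based half-open, plus strand."""
        ivs = sorted((qs, qs + ln) for qs, _, ln in self.blocks)
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged


def _parse_int_list(text: str, line_no: int, what: str) -> list[int]:
    try:
        return [int(x) for x in text.rstrip(",").split(",") if x]
    except ValueError as exc:
        raise PslParseError(f"line {line_no}: non-numeric {what}: {text!r}") from exc


def read_psl(source: str | Path | TextIO | Iterable[str]) -> list[AlignmentRecord]:
    """Parse a PSL file or stream (with or without the 5-line header)."""
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return read_psl(handle)
    records: list[AlignmentRecord] = []
    for line_no, line in enumerate(source, 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(("psLayout", "match", "-----", " ")):
            continue  # header lines
        fields = line.split("\t")
        if len(fields) != PSL_COLUMNS:
            raise PslParseError(
                f"line {line_no}: expected {PSL_COLUMNS} columns, got {len(fields)}"
            )
        try:
            match, mismatch, _rep, _ncount = (int(x) for x in fields[0:4])
            q_gap_count, q_gap_bases, t_gap_count, t_gap_bases = (
                int(x) for x in fields[4:8]
            )
            strand = fields[8]
            q_name, q_size, q_start, q_end = (
                fields[9], int(fields[10]), int(fields[11]), int(fields[12]),
            )
            t_name, t_size, t_start, t_end = (
                fields[13], int(fields[14]), int(fields[15]), int(fields[16]),
            )
            block_count = int(fields[17])
        except ValueError as exc:
            raise PslParseError(f"line {line_no}: non-numeric field: {exc}") from exc
        sizes = _parse_int_list(fields[18], line_no, "blockSizes")
        q_starts = _parse_int_list(fields[19], line_no, "qStarts")
        t_starts = _parse_int_list(fields[20], line_no, "tStarts")
        if not len(sizes) == len(q_starts) == len(t_starts) == block_count:
            raise PslParseError(f"line {line_no}: block list lengths != blockCount")
        if strand == "-":
            # PSL stores minus-strand query starts in rc coordinates
            q_starts = [q_size - (qs + ln) for qs, ln in zip(q_starts, sizes)]
        blocks = tuple(zip(q_starts, t_starts, sizes))
        records.append(
            AlignmentRecord(
                q_name=q_name, t_name=t_name, strand=strand,
                match=match, mismatch=mismatch,
                q_gap_count=q_gap_count, q_gap_bases=q_gap_bases,
                t_gap_count=t_gap_count, t_gap_bases=t_gap_bases,
                q_size=q_size, q_start=q_start, q_end=q_end,
                t_size=t_size, t_start=t_start, t_end=t_end,
                blocks=blocks,
            )
        )
    return records


def write_psl(records: list[AlignmentRecord], dest: str | Path | TextIO) -> None:
    """Write records as header-less 21-column PSL."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as handle:
            write_psl(records, handle)
        return
    for r in records:
        sizes = [ln for _, _, ln in r.blocks]
        q_starts = [qs for qs, _, _ in r.blocks]
        t_starts = [ts for _, ts, _ in r.blocks]
        if r.strand == "-":
            q_starts = [r.q_size - (qs + ln) for qs, ln in zip(q_starts, sizes)]
        fields = [
            r.match, r.mismatch, 0, 0,
            r.q_gap_count, r.q_gap_bases, r.t_gap_count, r.t_gap_bases,
            r.strand, r.q_name, r.q_size, r.q_start, r.q_end,
            r.t_name, r.t_size, r.t_start, r.t_end,
            len(r.blocks),
            ",".join(map(str, sizes)) + ",",
            ",".join(map(str, q_starts)) + ",",
            ",".join(map(str, t_starts)) + ",",
        ]
        dest.write("\t".join(map(str, fields)) + "\n")
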