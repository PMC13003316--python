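"""FASTA input and BED / masked-FASTA output."""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

from Bio import SeqIO

from .finder import LcInterval

__all__ = [
    "SequenceRecord",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "write_masked_fasta",
    "gc_fraction",
]


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence; bases are uppercased, ambiguity preserved."""

    id: str
    bases: str

    def __len__(self) -> int:
        return len(self.bases)


class FastaParseError(ValueError):
    pass


def _open_text(path) -> TextIO:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a plain or gzip FASTA file.

    Record names are the first whitespace-delimited token of the header;
    sequences are uppercased.  Sequence data before the first header is a
    parse error reported with its line number.
    """
    with _open_text(path) as fh:
        # Bio.SeqIO silently drops leading junk; check the preamble here
        lines = []
        for lineno, line in enumerate(fh, start=1):
            if not lines and line.strip() and not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before "
                    "the first FASTA header"
                )
            lines.append(line)
    records = [
        SequenceRecord(id=rec.id, bases=str(rec.seq).upper())
        for rec in SeqIO.parse(io.StringIO("".join(lines)), "fasta")
    ]
    seen = set()
    for rec in records:
        if not rec.id:
            raise FastaParseError(f"{path}: empty record name")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record name {rec.id!r}")
        seen.add(rec.id)
    return records


def gc_fraction(records: Iterable[SequenceRecord]) -> float:
    """Genome-wide G+C fraction over all records, counting ACGT only."""
    gc = at = 0
    for rec in records:
        b = rec.bases
        gc += b.count("G") + b.count("C")
        at += b.count("A") + b.count("T")
    total = gc + at
    if total == 0:
        raise ValueError("no ACGT bases in input; cannot estimate GC")
    return gc / total


def write_bed(intervals: Sequence[LcInterval], sink: TextIO) -> None:
    """Standard 3-column BED, 0-based half-open, one merged interval per
    line, in the given order."""
    for iv in intervals:
        sink.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\n")


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(records: Sequence[SequenceRecord], sink: TextIO) -> None:
    for rec in records:
        sink.write(f">{rec.id}\n{_wrap(rec.bases)}\n")


def write_masked_fasta(
    records: Sequence[SequenceRecord],
    intervals: Sequence[LcInterval],
    sink: TextIO,
    hard: bool = False,
) -> None:
    """Write records with interval bases soft-masked (lowercase) or
    hard-masked (N); 60-column lines."""
    by_seq: dict[str, list[LcInterval]] = {}
    names = {rec.id for rec in records}
    for iv in intervals:
        if iv.seq_id not in names:
            raise KeyError(f"interval references unknown sequence {iv.seq_id!r}")
        by_seq.setdefault(iv.seq_id, []).append(iv)
    for rec in records:
        chars = list(rec.bases)
        for iv in by_seq.get(rec.id, ()):
            if iv.end > len(chars):
                raise IndexError(
                    f"interval [{iv.start}, {iv.end}) exceeds {rec.id} "
                    f"length {len(chars)}"
                )
            for p in range(iv.start, iv.end):
                chars[p] = "N" if hard else chars[p].lower()
        sink.write(f">{rec.id}\n{_wrap(''.join(chars))}\n")
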