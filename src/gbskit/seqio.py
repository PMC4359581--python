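"""Streaming FASTA / FASTQ / BED input and output.

All higher-level modules (digest, demultiplex, discovery, simulate) read and
write sequence data through this module.  FASTQ files may be plain text or
gzip-compressed; compression is detected from the first two bytes of the file
(the gzip magic number), never from the file extension.  Sequences are
uppercased on ingest so that downstream matching is case-insensitive; quality
strings are never altered and are assumed to be Phred+33 encoded.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadRecord",
    "FastaRecord",
    "BedInterval",
    "FastqFormatError",
    "FastaFormatError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "reverse_complement",
    "mean_phred_quality",
]

_GZIP_MAGIC = b"\x1f\x8b"

_READ_ALPHABET = frozenset("ACGTN")

# full IUPAC nucleotide complement, used for reads and degenerate patterns alike
_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


class FastqFormatError(ValueError):
    """Raised for structurally invalid FASTQ input."""


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input."""


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read: identifier, sequence and Phred+33 quality."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) != len(self.quality):
            raise FastqFormatError(
                f"record {self.id!r}: sequence length {len(seq)} != "
                f"quality length {len(self.quality)}"
            )
        if not _READ_ALPHABET.issuperset(seq):
            bad = sorted(set(seq) - _READ_ALPHABET)
            raise FastqFormatError(
                f"record {self.id!r}: invalid sequence character(s) {bad}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int | None = None) -> "ReadRecord":
        """Return a sub-read with sequence and quality cut identically."""
        return ReadRecord(self.id, self.sequence[start:end], self.quality[start:end])


@dataclass(frozen=True)
class FastaRecord:
    """A named nucleotide sequence (IUPAC codes allowed)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BedInterval:
    """A 0-based half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid BED interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mean_phred_quality(quality: str) -> float:
    """Mean Phred score of a +33-encoded quality string (0.0 if empty)."""
    if not quality:
        return 0.0
    return sum(ord(c) - 33 for c in quality) / len(quality)


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    """Open text for reading, transparently decompressing gzip input.

    Detection uses the two gzip magic bytes, not the file name.
    """
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == _GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    return io.TextIOWrapper(raw)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a plain or gzipped FASTQ file."""
    with _open_maybe_gzip(path) as handle:
        index = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                index += 1
                yield ReadRecord(title.split(None, 1)[0], seq, qual)
        except ValueError as exc:  # Biopython's malformed-block errors
            raise FastqFormatError(
                f"{path}: malformed FASTQ at record {index + 1}: {exc}"
            ) from exc


def write_fastq(
    records: Iterable[ReadRecord], path: str | Path, compress: bool = False
) -> int:
    """Write records as 4-line FASTQ; returns the number of records written."""
    opener = gzip.open if compress else open
    n = 0
    with opener(path, "wt") as handle:
        for rec in records:
            handle.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> Iterator[FastaRecord]:
    """Stream FastaRecords; multi-line sequences are concatenated.

    Sequence data before the first ``>`` header is an error.
    """
    with _open_maybe_gzip(path) as handle:
        header: str | None = None
        chunks: list[str] = []
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    yield FastaRecord(header, "".join(chunks))
                header = line[1:].split(None, 1)[0]
                chunks = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}: line {lineno}: sequence before first '>' header"
                    )
                chunks.append(line)
        if header is not None:
            yield FastaRecord(header, "".join(chunks))


def write_fasta(
    records: Iterable[FastaRecord], path: str | Path, width: int = 80
) -> int:
    n = 0
    with open(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")
            n += 1
    return n


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> int:
    """Write BED4 (chrom, start, end, name); returns the interval count."""
    n = 0
    with open(path, "wt") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            n += 1
    return n
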