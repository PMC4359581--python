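"""Candidate in-line barcode discovery from raw or undetermined FASTQ.

For every read and every candidate length L, the first L bases are counted
as a potential barcode when a known enzyme's recognition site follows them
exactly (IUPAC-aware, no mismatches — discovery is exploratory counting and
mismatch tolerance would multiply spurious candidates).  Optionally, every
prefix is also counted unconditionally under the pseudo-enzyme ``none``.
One tab-delimited table per length is produced, sorted by descending count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .enzymes import EnzymeTable, compiled_pattern
from .seqio import read_fastq

__all__ = ["DiscoveryResult", "discover_barcodes", "write_discovery_tables"]

NO_ENZYME = "none"


@dataclass
class DiscoveryResult:
    min_len: int
    max_len: int
    #: length -> Counter of (barcode, enzyme name) -> read count
    counts: dict[int, "Counter[tuple[str, str]]"] = field(default_factory=dict)
    #: length -> reads skipped because the prefix contained N
    skipped: dict[int, int] = field(default_factory=dict)
    total_reads: int = 0

    def top(self, length: int, n: int) -> list[tuple[str, str, int]]:
        return [
            (bc, enz, cnt)
            for (bc, enz), cnt in self.counts[length].most_common(n)
        ]


def discover_barcodes(
    fastq: str | Path,
    enzyme_table: EnzymeTable,
    min_len: int = 6,
    max_len: int = 16,
    include_no_enzyme: bool = False,
) -> DiscoveryResult:
    """Count candidate barcodes of each length in ``[min_len, max_len]``."""
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    result = DiscoveryResult(min_len, max_len)
    lengths = range(min_len, max_len + 1)
    for length in lengths:
        result.counts[length] = Counter()
        result.skipped[length] = 0
    patterns = [(enz.name, compiled_pattern(enz.recognition)) for enz in enzyme_table]
    for read in read_fastq(fastq):
        result.total_reads += 1
        seq = read.sequence
        for length in lengths:
            if len(seq) < length:
                continue
            prefix = seq[:length]
            if "N" in prefix:
                result.skipped[length] += 1
                continue
            counter = result.counts[length]
            for name, sets in patterns:
                end = length + len(sets)
                if end > len(seq):
                    continue
                if all(seq[length + j] in allowed for j, allowed in enumerate(sets)):
                    counter[(prefix, name)] += 1
            if include_no_enzyme:
                counter[(prefix, NO_ENZYME)] += 1
    return result


def write_discovery_tables(result: DiscoveryResult, outdir: str | Path) -> list[Path]:
    """One ``barcodes_L<length>.tsv`` per candidate length."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for length in range(result.min_len, result.max_len + 1):
        path = outdir / f"barcodes_L{length}.tsv"
        rows = sorted(
            result.counts[length].items(), key=lambda kv: (-kv[1], kv[0])
        )
        with open(path, "wt") as handle:
            handle.write("barcode\tenzyme\tcount\n")
            for (bc, enz), cnt in rows:
                handle.write(f"{bc}\t{enz}\t{cnt}\n")
        paths.append(path)
    return paths
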