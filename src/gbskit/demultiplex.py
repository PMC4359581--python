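"""In-line barcode demultiplexing and read trimming.

Reads are assigned to samples by comparing the read start against each
sample's probe: the barcode alone (``inline`` mode) or barcode + restriction
recognition site (``rad`` and ``gbs`` modes).  Barcode mismatches are counted
plainly; recognition-site mismatches are IUPAC-aware.  A sample is a
candidate when both counts are within their budgets (default 1 + 1); the
winner has the fewest barcode mismatches, then the fewest enzyme mismatches,
then the longest barcode, and a remaining tie is written to undetermined.

Matched reads are trimmed at the 5' end (barcode, plus recognition site
unless ``keep_enzyme_5prime``), then at the 3' end for adapter read-through:

* ``gbs``  — first position where the recognition site matches followed by
  the start of the common adapter (partial adapter allowed at the read end,
  mismatch budget proportional to the compared length);
* ``rad``  — first adapter match (>= 3 bases of overlap);
* ``inline`` — adapter-only trimming when an adapter is supplied.

Read 2 of a pair is trimmed at the recognition site followed by the reverse
complement of the sample's barcode.  Because GBS inserts are short, both
reads of a pair should end at the same template position; a consistency step
compares trimmed lengths, checks the read-through overlap, and either trims
the longer read down or restores the shorter read from its untrimmed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .enzymes import Enzyme, EnzymeTable, compiled_pattern, site_mismatches
from .seqio import ReadRecord, mean_phred_quality, read_fastq, reverse_complement, write_fastq

__all__ = [
    "SampleSheet",
    "SampleRow",
    "DemuxConfig",
    "MatchResult",
    "UNDETERMINED",
    "DemuxStats",
    "SampleSheetError",
    "match_read",
    "trim_5prime",
    "trim_3prime_read1",
    "trim_3prime_read2",
    "reconcile_pair",
    "demultiplex_run",
]

UNDETERMINED = "undetermined"

_MODES = ("inline", "rad", "gbs")


class SampleSheetError(ValueError):
    """Raised for invalid sample sheets."""


@dataclass(frozen=True)
class SampleRow:
    sample: str
    barcode: str
    enzyme_name: str = ""


@dataclass
class SampleSheet:
    rows: list[SampleRow]

    def __post_init__(self) -> None:
        samples = [r.sample for r in self.rows]
        barcodes = [r.barcode for r in self.rows]
        if len(set(samples)) != len(samples):
            raise SampleSheetError("duplicate sample names in sheet")
        if len(set(barcodes)) != len(barcodes):
            raise SampleSheetError("duplicate barcodes in sheet")
        for r in self.rows:
            if not r.barcode or not set(r.barcode) <= set("ACGT"):
                raise SampleSheetError(
                    f"sample {r.sample!r}: barcode {r.barcode!r} is not ACGT"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "SampleSheet":
        rows = []
        with open(path) as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = [f.strip() for f in line.split("\t")]
                if len(fields) < 2:
                    raise SampleSheetError(
                        f"{path}: expected sample<TAB>barcode[<TAB>enzyme]: {line!r}"
                    )
                rows.append(
                    SampleRow(
                        fields[0],
                        fields[1].upper(),
                        fields[2] if len(fields) > 2 else "",
                    )
                )
        return cls(rows)

    def max_barcode_length(self) -> int:
        return max(len(r.barcode) for r in self.rows)


@dataclass
class DemuxConfig:
    mode: str = "gbs"
    barcode_mismatches: int = 1
    enzyme_mismatches: int = 1
    common_adapter: str | None = None
    adapter_mismatch_rate: float = 0.1
    keep_enzyme_5prime: bool = False
    paired: bool = False
    #: adapter-only trimming needs this many adapter bases unless flush-fitted
    min_adapter_overlap: int = 3
    #: read-2 barcode trimming needs this many barcode bases visible
    min_barcode_overlap: int = 3

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.common_adapter is not None:
            self.common_adapter = self.common_adapter.upper()


@dataclass(frozen=True)
class MatchResult:
    sample: str  # sample name or UNDETERMINED
    barcode: str = ""
    barcode_mismatches: int = -1
    enzyme_mismatches: int = -1
    prefix_length: int = 0  # bases to remove at the 5' end

    @property
    def assigned(self) -> bool:
        return self.sample != UNDETERMINED


NO_MATCH = MatchResult(UNDETERMINED)


class _Probe:
    __slots__ = ("sample", "barcode", "enzyme", "probe_len")

    def __init__(self, sample: str, barcode: str, enzyme: Enzyme | None):
        self.sample = sample
        self.barcode = barcode
        self.enzyme = enzyme
        self.probe_len = len(barcode) + (len(enzyme.recognition) if enzyme else 0)


def _build_probes(
    sheet: SampleSheet, config: DemuxConfig, enzyme_table: EnzymeTable | None
) -> list[_Probe]:
    probes = []
    for row in sheet.rows:
        enzyme = None
        if config.mode != "inline":
            if not row.enzyme_name:
                raise SampleSheetError(
                    f"sample {row.sample!r}: mode {config.mode!r} requires an enzyme"
                )
            if enzyme_table is None:
                raise SampleSheetError("enzyme table required in rad/gbs mode")
            enzyme = enzyme_table.get(row.enzyme_name)  # KeyError if unknown
        probes.append(_Probe(row.sample, row.barcode, enzyme))
    return probes


def _match_probes(read: ReadRecord, probes: list[_Probe], config: DemuxConfig) -> MatchResult:
    seq = read.sequence
    best: tuple[int, int, int] | None = None
    best_probe: _Probe | None = None
    tie = False
    for probe in probes:
        if len(seq) < probe.probe_len:
            continue
        bc = probe.barcode
        bc_mm = sum(a != b for a, b in zip(bc, seq))
        if bc_mm > config.barcode_mismatches:
            continue
        enz_mm = 0
        if probe.enzyme is not None:
            rec = probe.enzyme.recognition
            enz_mm = site_mismatches(rec, seq[len(bc) : len(bc) + len(rec)])
            if enz_mm > config.enzyme_mismatches:
                continue
        key = (bc_mm, enz_mm, -len(bc))
        if best is None or key < best:
            best, best_probe, tie = key, probe, False
        elif key == best:
            tie = True
    if best is None or best_probe is None or tie:
        return NO_MATCH
    trim = len(best_probe.barcode)
    if best_probe.enzyme is not None and not config.keep_enzyme_5prime:
        trim += len(best_probe.enzyme.recognition)
    return MatchResult(
        best_probe.sample, best_probe.barcode, best[0], best[1], trim
    )


def match_read(
    read: ReadRecord,
    sheet: SampleSheet,
    config: DemuxConfig,
    enzyme_table: EnzymeTable | None = None,
) -> MatchResult:
    """Assign one read; convenience wrapper building probes per call."""
    return _match_probes(read, _build_probes(sheet, config, enzyme_table), config)


def trim_5prime(read: ReadRecord, match: MatchResult) -> ReadRecord:
    """Remove the matched barcode (and site) from sequence and quality."""
    if not match.assigned:
        raise ValueError("cannot 5'-trim an undetermined read")
    return read.slice(match.prefix_length)


def _site_match_at(
    sets: tuple[frozenset[str], ...], seq: str, start: int, budget: int
) -> bool:
    """IUPAC site comparison with early exit once the budget is exceeded."""
    mm = 0
    for j, allowed in enumerate(sets):
        if seq[start + j] not in allowed:
            mm += 1
            if mm > budget:
                return False
    return True


def _adapter_overlap_ok(
    seq: str, start: int, adapter: str, rate: float
) -> bool:
    """Partial-prefix adapter comparison with a proportional mismatch budget."""
    a = min(len(adapter), len(seq) - start)
    if a < 0:
        return False
    budget = int(a * rate)
    mm = sum(seq[start + i] != adapter[i] for i in range(a))
    return mm <= budget


def trim_3prime_read1(
    read: ReadRecord, enzyme: Enzyme | None, config: DemuxConfig
) -> tuple[ReadRecord, bool]:
    """3' trim of read 1 (or a single-end read); returns (read, trimmed?)."""
    seq = read.sequence
    adapter = config.common_adapter
    if config.mode == "gbs":
        if enzyme is None:
            raise ValueError("gbs mode requires an enzyme")
        sets = compiled_pattern(enzyme.recognition)
        rlen = len(sets)
        budget = config.enzyme_mismatches
        for i in range(len(seq) - rlen + 1):
            if not _site_match_at(sets, seq, i, budget):
                continue
            # a = 0 happens when the site ends flush with the read
            if adapter is None or _adapter_overlap_ok(
                seq, i + rlen, adapter, config.adapter_mismatch_rate
            ):
                return read.slice(0, i), True
        return read, False
    if adapter is None:
        return read, False
    # rad / inline: adapter-only trimming, minimum overlap unless flush-fitted
    min_overlap = min(config.min_adapter_overlap, len(adapter))
    max_budget = int(len(adapter) * config.adapter_mismatch_rate)
    a0, a1 = adapter[0], adapter[1] if len(adapter) > 1 else ""
    for i in range(len(seq) - min_overlap + 1):
        # cheap prefilter: with budget <= 1, >=2 mismatches in the first two
        # compared bases already disqualify this position
        if max_budget <= 1 and seq[i] != a0 and a1 and seq[i + 1] != a1:
            continue
        if _adapter_overlap_ok(seq, i, adapter, config.adapter_mismatch_rate):
            return read.slice(0, i), True
    return read, False


def trim_3prime_read2(
    read2: ReadRecord,
    enzyme: Enzyme | None,
    barcode: str,
    config: DemuxConfig,
) -> tuple[ReadRecord, bool]:
    """3' trim of read 2: recognition site + reverse-complemented barcode.

    In inline mode (no enzyme) read 2 falls back to adapter-only trimming.
    At the read end a partial barcode is accepted down to
    ``min_barcode_overlap`` bases, under the full ``barcode_mismatches``
    budget.  When the barcode is fully visible and a common adapter is
    configured, the bases after it must also match the adapter start (same
    partial-overlap rule as read 1): genuine read-through always continues
    into the adapter, and the extra anchor stops chance site+barcode
    lookalikes inside the insert from truncating the read.
    """
    if enzyme is None:
        return trim_3prime_read1(read2, None, config)
    seq = read2.sequence
    sets = compiled_pattern(enzyme.recognition)
    rlen = len(sets)
    rc_bc = reverse_complement(barcode)
    min_overlap = min(config.min_barcode_overlap, len(rc_bc))
    for i in range(len(seq) - rlen + 1):
        if not _site_match_at(sets, seq, i, config.enzyme_mismatches):
            continue
        a = min(len(rc_bc), len(seq) - i - rlen)
        if a < min_overlap:
            continue
        mm = sum(seq[i + rlen + j] != rc_bc[j] for j in range(a))
        if mm > config.barcode_mismatches:
            continue
        if a == len(rc_bc) and config.common_adapter is not None:
            if not _adapter_overlap_ok(
                seq, i + rlen + a, config.common_adapter,
                config.adapter_mismatch_rate,
            ):
                continue
        return read2.slice(0, i), True
    return read2, False


def reconcile_pair(
    read1: ReadRecord,
    read2: ReadRecord,
    original1: ReadRecord,
    original2: ReadRecord,
    enzyme: Enzyme | None,
    max_barcode_len: int,
    config: DemuxConfig,
) -> tuple[ReadRecord, ReadRecord]:
    """Paired-end trimming consistency correction.

    ``original1``/``original2`` are the 5'-trimmed but 3'-untrimmed reads.
    When trimmed lengths differ, the pair overlap is checked: the start of
    the longer read must be the reverse complement of the end of the shorter
    read (window: recognition length + longest barcode, mismatch budget:
    enzyme + barcode budgets).  On success the longer read is cut to the
    shorter length; on failure the longer read is trusted and the shorter
    read is re-cut from its untrimmed form.
    """
    if len(read1) == len(read2):
        return read1, read2
    if len(read1) > len(read2):
        r_long, r_short = read1, read2
        orig_short, short_is_r2 = original2, True
    else:
        r_long, r_short = read2, read1
        orig_short, short_is_r2 = original1, False
    window = max_barcode_len + (len(enzyme.recognition) if enzyme else 0)
    k = min(window, len(r_short))
    budget = config.enzyme_mismatches + config.barcode_mismatches
    if k > 0:
        head = r_long.sequence[:k]
        tail_rc = reverse_complement(r_short.sequence[-k:])
        if sum(a != b for a, b in zip(head, tail_rc)) <= budget:
            r_long = r_long.slice(0, len(r_short))
            return (r_long, r_short) if short_is_r2 else (r_short, r_long)
    r_short = orig_short.slice(0, len(r_long))
    return (r_long, r_short) if short_is_r2 else (r_short, r_long)


@dataclass
class SampleStats:
    reads: int = 0
    mismatch_counts: dict[int, int] = field(default_factory=dict)
    basepairs: int = 0
    quality_sum: float = 0.0
    quality_bases: int = 0

    def mean_quality(self) -> float:
        return self.quality_sum / self.quality_bases if self.quality_bases else 0.0


@dataclass
class DemuxStats:
    total: int = 0
    undetermined: int = 0
    per_sample: dict[str, SampleStats] = field(default_factory=dict)

    def assigned(self) -> int:
        return self.total - self.undetermined

    def to_tsv(self) -> str:
        max_mm = 0
        for s in self.per_sample.values():
            if s.mismatch_counts:
                max_mm = max(max_mm, max(s.mismatch_counts))
        mm_cols = "\t".join(f"mismatch_{i}" for i in range(max_mm + 1))
        lines = [
            f"sample\treads\tpercent\t{mm_cols}\tbasepairs\tmean_quality"
        ]
        for name in sorted(self.per_sample):
            s = self.per_sample[name]
            pct = 100.0 * s.reads / self.total if self.total else 0.0
            mms = "\t".join(
                str(s.mismatch_counts.get(i, 0)) for i in range(max_mm + 1)
            )
            lines.append(
                f"{name}\t{s.reads}\t{pct:.2f}\t{mms}\t{s.basepairs}\t"
                f"{s.mean_quality():.2f}"
            )
        pct = 100.0 * self.undetermined / self.total if self.total else 0.0
        blank = "\t".join("" for _ in range(max_mm + 1))
        lines.append(f"{UNDETERMINED}\t{self.undetermined}\t{pct:.2f}\t{blank}\t\t")
        return "\n".join(lines) + "\n"


class _LazyWriters:
    """Per-sample FASTQ writers, opened on first use."""

    def __init__(self, outdir: Path, paired: bool, compress: bool):
        self.outdir = outdir
        self.paired = paired
        self.compress = compress
        self._handles: dict[str, list] = {}

    def _open(self, name: str):
        import gzip as _gzip

        ext = ".fastq.gz" if self.compress else ".fastq"
        opener = _gzip.open if self.compress else open
        handles = [opener(self.outdir / f"{name}.R1{ext}", "wt")]
        if self.paired:
            handles.append(opener(self.outdir / f"{name}.R2{ext}", "wt"))
        self._handles[name] = handles
        return handles

    def write(self, name: str, r1: ReadRecord, r2: ReadRecord | None) -> None:
        handles = self._handles.get(name) or self._open(name)
        handles[0].write(f"@{r1.id}\n{r1.sequence}\n+\n{r1.quality}\n")
        if r2 is not None:
            handles[1].write(f"@{r2.id}\n{r2.sequence}\n+\n{r2.quality}\n")

    def close(self) -> None:
        for handles in self._handles.values():
            for h in handles:
                h.close()


def _paired_iterator(path1, path2) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    it1, it2 = read_fastq(path1), read_fastq(path2)
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise ValueError("paired FASTQ files have unequal record counts")
        yield r1, r2


def demultiplex_run(
    fastq1: str | Path,
    fastq2: str | Path | None,
    sheet: SampleSheet | str | Path,
    config: DemuxConfig,
    outdir: str | Path,
    enzyme_table: EnzymeTable | None = None,
    compress: bool = False,
) -> DemuxStats:
    """Demultiplex a run into per-sample FASTQ files plus statistics.

    Every input read (pair) lands in exactly one sample file or in the
    undetermined file; undetermined reads are written untrimmed so that
    barcode discovery can be run on them.  The stats table is written to
    ``<outdir>/demux_stats.tsv``.
    """
    if isinstance(sheet, (str, Path)):
        sheet = SampleSheet.from_file(sheet)
    paired = fastq2 is not None
    config.paired = paired
    probes = _build_probes(sheet, config, enzyme_table)
    probe_by_sample = {p.sample: p for p in probes}
    max_bc = sheet.max_barcode_length()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stats = DemuxStats()
    writers = _LazyWriters(outdir, paired, compress)
    try:
        source: Iterable
        if paired:
            source = _paired_iterator(fastq1, fastq2)
        else:
            source = ((r, None) for r in read_fastq(fastq1))
        for r1, r2 in source:
            stats.total += 1
            match = _match_probes(r1, probes, config)
            if not match.assigned:
                stats.undetermined += 1
                writers.write(UNDETERMINED, r1, r2)
                continue
            probe = probe_by_sample[match.sample]
            enzyme = probe.enzyme
            t1 = trim_5prime(r1, match)
            if r2 is not None:
                t2 = r2
                if (
                    enzyme is not None
                    and not config.keep_enzyme_5prime
                    and len(t2) >= len(enzyme.recognition)
                    and site_mismatches(
                        enzyme.recognition, t2.sequence[: len(enzyme.recognition)]
                    )
                    <= config.enzyme_mismatches
                ):
                    t2 = t2.slice(len(enzyme.recognition))
                orig1, orig2 = t1, t2
                t1, trimmed1 = trim_3prime_read1(t1, enzyme, config)
                t2, trimmed2 = trim_3prime_read2(t2, enzyme, match.barcode, config)
                if trimmed1 or trimmed2:
                    t1, t2 = reconcile_pair(
                        t1, t2, orig1, orig2, enzyme, max_bc, config
                    )
            else:
                t2 = None
                t1, _ = trim_3prime_read1(t1, enzyme, config)
            sstats = stats.per_sample.setdefault(match.sample, SampleStats())
            sstats.reads += 1
            sstats.mismatch_counts[match.barcode_mismatches] = (
                sstats.mismatch_counts.get(match.barcode_mismatches, 0) + 1
            )
            for rec in (t1, t2):
                if rec is not None:
                    sstats.basepairs += len(rec)
                    sstats.quality_sum += sum(ord(c) - 33 for c in rec.quality)
                    sstats.quality_bases += len(rec)
            writers.write(match.sample, t1, t2)
    finally:
        writers.close()
    # make sure every sheet sample appears in the stats even with zero reads
    for row in sheet.rows:
        stats.per_sample.setdefault(row.sample, SampleStats())
    with open(outdir / "demux_stats.tsv", "wt") as handle:
        handle.write(stats.to_tsv())
    return stats
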