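"""GBS read simulation with ground truth, and demultiplexing evaluation.

The simulator turns a set of restriction fragments (every fragment starts
and ends with a recognition-site match) and a set of barcodes into
single-end or paired-end FASTQ with the exact library geometry the
demultiplexer is built for:

* read 1 template:  barcode + fragment + common adapter + poly-A padding
* read 2 template:  revcomp(barcode + fragment) + common adapter + poly-A
  (so read 2 runs through the reverse-complemented barcode before the
  adapter, as paired-end read-through of a short insert does)

Half of the reads of each (sample, fragment) are generated from each
fragment end (the right-end reads use the reverse-complemented fragment).
Sequencing noise is an independent per-base substitution with probability
``error_rate``; the error base becomes a uniformly random different symbol
from {A, C, G, T, N}.  Qualities are constant 'I' (Phred 40).  Every read
carries its truth in the read id and in a tab-delimited truth table, making
evaluation independent of read order.

The evaluator reproduces the published benchmark protocol: sensitivity =
correctly assigned / total simulated units; misassignments per million
reads; and trimming correctness by comparing each output read's length with
the length a perfect trimmer would produce (any deviation, over- or
under-trimming, counts as incorrect).  Trimming sensitivity and trimming
errors per thousand are computed over the correctly demultiplexed units.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from random import Random
from typing import Iterable, Sequence

from .demultiplex import DemuxConfig, UNDETERMINED
from .digest import DigestConfig, find_site_matches, select_fragments, digest_genome
from .digest import fragments_from_cuts, find_cut_sites
from .enzymes import Enzyme, IUPAC
from .seqio import FastaRecord, read_fasta, read_fastq, reverse_complement, write_fasta

__all__ = [
    "DEFAULT_ADAPTER",
    "SimConfig",
    "TruthRow",
    "SimResult",
    "EvalReport",
    "random_fragment_set",
    "fragments_from_reference",
    "build_fragment_fasta",
    "simulate_reads",
    "load_truth",
    "expected_trimmed_lengths",
    "evaluate_demux",
    "percentage",
    "per_million",
    "per_thousand",
]

_NUCS = "ACGT"
_ERROR_SYMBOLS = "ACGTN"
_QUALITY_CHAR = "I"

#: default Illumina common-adapter start used by the benchmark (14 bp)
DEFAULT_ADAPTER = "AGATCGGAAGAGCG"


# ---------------------------------------------------------------------------
# fragment construction


def _expand_pattern(pattern: str, rng: Random) -> str:
    """A concrete realisation of an IUPAC pattern (degenerate codes drawn)."""
    return "".join(sorted(IUPAC[c])[rng.randrange(len(IUPAC[c]))] for c in pattern)


def random_fragment_set(
    n: int,
    enzyme: Enzyme,
    min_len: int,
    max_len: int,
    seed: int | None = None,
) -> list[FastaRecord]:
    """Synthesise ``n`` restriction fragments with no reference genome.

    Each fragment is (concrete site) + random insert + (concrete site), with
    lengths uniform over [min_len, max_len].  Candidates containing an
    additional internal recognition match are redrawn, because a real digest
    cannot leave an intact internal site.
    """
    rlen = len(enzyme.recognition)
    if min_len < 2 * rlen:
        raise ValueError(f"min_len must be >= {2 * rlen} (two full sites)")
    rng = Random(seed)
    fragments: list[FastaRecord] = []
    for i in range(n):
        length = rng.randint(min_len, max_len)
        while True:
            left = _expand_pattern(enzyme.recognition, rng)
            right = _expand_pattern(enzyme.recognition, rng)
            middle = "".join(rng.choice(_NUCS) for _ in range(length - 2 * rlen))
            seq = left + middle + right
            matches = find_site_matches(seq, enzyme)
            if matches == [0, length - rlen] or (
                length == 2 * rlen and 0 in matches
            ):
                break
        fragments.append(FastaRecord(f"frag{i:04d}", seq))
    return fragments


def fragments_from_reference(
    fasta_path: str | Path,
    enzyme: Enzyme,
    min_fragment: int,
    max_fragment: int,
) -> list[FastaRecord]:
    """Digest a reference and extract size-selected fragment sequences.

    Fragment frames are extended so both complete recognition sites are
    included (left by the cut offset, right by site length - cut offset),
    matching the simulator's requirement that every fragment start and end
    with a site match.
    """
    config = DigestConfig(min_fragment=min_fragment, max_fragment=max_fragment)
    records: list[FastaRecord] = []
    rlen = len(enzyme.recognition)
    for record in read_fasta(fasta_path):
        cuts = find_cut_sites(record, enzyme)
        frags = fragments_from_cuts(record.id, len(record), cuts)
        for frag in select_fragments(frags, config):
            start = frag.start - enzyme.cut_offset
            end = frag.end + (rlen - enzyme.cut_offset)
            if start < 0 or end > len(record):
                continue  # site truncated by the contig boundary
            records.append(
                FastaRecord(
                    f"{record.id}_{frag.start}_{frag.end}",
                    record.sequence[start:end],
                )
            )
    return records


def build_fragment_fasta(
    out_path: str | Path,
    enzyme: Enzyme,
    reference: str | Path | None = None,
    n_random: int | None = None,
    min_len: int = 60,
    max_len: int = 200,
    seed: int | None = None,
) -> int:
    """Write a fragment FASTA from a reference digest or from random draws."""
    if (reference is None) == (n_random is None):
        raise ValueError("give exactly one of reference / n_random")
    if reference is not None:
        frags = fragments_from_reference(reference, enzyme, min_len, max_len)
    else:
        frags = random_fragment_set(n_random, enzyme, min_len, max_len, seed)
    return write_fasta(frags, out_path)


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SimConfig:
    read_length: int = 100
    reads_per_locus: int = 4  # total reads (or pairs) per sample per fragment
    paired: bool = True
    error_rate: float = 0.01
    common_adapter: str = DEFAULT_ADAPTER
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.reads_per_locus <= 0 or self.reads_per_locus % 2:
            raise ValueError("reads_per_locus must be a positive even integer")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")


@dataclass(frozen=True)
class TruthRow:
    read_id: str
    sample: str
    fragment_id: str
    end: str  # "L" or "R"
    barcode: str
    fragment_length: int
    barcode_errors: int  # substitutions that landed in read 1's barcode span
    enzyme_errors: int  # substitutions in read 1's leading recognition site


@dataclass
class SimResult:
    fastq1: Path
    fastq2: Path | None
    truth_path: Path
    summary_path: Path
    reads: int = 0
    barcode_error_histogram: dict[int, int] = field(default_factory=dict)


def _mutate(seq: str, rng: Random, error_rate: float) -> tuple[str, list[int]]:
    """Apply per-base substitutions; returns (sequence, error positions)."""
    if error_rate == 0.0:
        return seq, []
    chars = list(seq)
    positions = []
    for i, c in enumerate(chars):
        if rng.random() < error_rate:
            alternatives = _ERROR_SYMBOLS.replace(c, "")
            chars[i] = alternatives[rng.randrange(len(alternatives))]
            positions.append(i)
    return "".join(chars), positions


def simulate_reads(
    fragments: Sequence[FastaRecord] | str | Path,
    barcodes: Sequence[tuple[str, str]],
    config: SimConfig,
    outdir: str | Path,
    sample_names: Sequence[str] | None = None,
) -> SimResult:
    """Simulate GBS reads for every (barcode, fragment) combination.

    ``barcodes`` is a list of (barcode sequence, enzyme name) pairs, one per
    sample.  Emits R1 (and R2 when paired) FASTQ, a truth TSV and a summary
    TSV into ``outdir``.  Fully deterministic for a fixed seed.
    """
    if isinstance(fragments, (str, Path)):
        fragments = list(read_fasta(fragments))
    if not fragments or not barcodes:
        raise ValueError("need at least one fragment and one barcode")
    if sample_names is None:
        sample_names = [f"S{i + 1:02d}" for i in range(len(barcodes))]
    L = config.read_length
    for bc, _ in barcodes:
        if len(bc) >= L:
            raise ValueError(f"barcode {bc} is not shorter than the read length")
    rng = Random(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fastq1 = outdir / "reads.R1.fastq"
    fastq2 = outdir / "reads.R2.fastq" if config.paired else None
    truth_path = outdir / "truth.tsv"
    summary_path = outdir / "sim_summary.tsv"
    per_end = config.reads_per_locus // 2
    qual = _QUALITY_CHAR * L
    result = SimResult(fastq1, fastq2, truth_path, summary_path)
    adapter = config.common_adapter
    with open(fastq1, "wt") as h1, (
        open(fastq2, "wt") if fastq2 else _null_handle()
    ) as h2, open(truth_path, "wt") as ht:
        ht.write(
            "read_id\tsample\tfragment_id\tend\tbarcode\tfragment_length\t"
            "barcode_errors\tenzyme_errors\n"
        )
        for (bc, enzyme_name), sample in zip(barcodes, sample_names):
            enz_len = _enzyme_site_length(enzyme_name)
            for frag in fragments:
                for end in ("L", "R"):
                    tmpl = (
                        frag.sequence
                        if end == "L"
                        else reverse_complement(frag.sequence)
                    )
                    t1 = (bc + tmpl + adapter + "A" * L)[:L]
                    t2 = (reverse_complement(bc + tmpl) + adapter + "A" * L)[:L]
                    for copy in range(per_end):
                        rid = f"{sample}:{frag.id}:{end}:{copy}"
                        s1, errs1 = _mutate(t1, rng, config.error_rate)
                        bc_errors = sum(1 for p in errs1 if p < len(bc))
                        enz_errors = sum(
                            1 for p in errs1 if len(bc) <= p < len(bc) + enz_len
                        )
                        h1.write(f"@{rid}\n{s1}\n+\n{qual}\n")
                        if config.paired:
                            s2, _ = _mutate(t2, rng, config.error_rate)
                            h2.write(f"@{rid}\n{s2}\n+\n{qual}\n")
                        ht.write(
                            f"{rid}\t{sample}\t{frag.id}\t{end}\t{bc}\t"
                            f"{len(frag.sequence)}\t{bc_errors}\t{enz_errors}\n"
                        )
                        result.reads += 1
                        result.barcode_error_histogram[bc_errors] = (
                            result.barcode_error_histogram.get(bc_errors, 0) + 1
                        )
    with open(summary_path, "wt") as hs:
        hs.write("metric\tvalue\n")
        hs.write(f"reads\t{result.reads}\n")
        hs.write(
            f"correct_barcodes\t{result.barcode_error_histogram.get(0, 0)}\n"
        )
        hs.write(
            f"one_mismatch_barcodes\t{result.barcode_error_histogram.get(1, 0)}\n"
        )
        more = sum(
            v for k, v in result.barcode_error_histogram.items() if k >= 2
        )
        hs.write(f"multi_mismatch_barcodes\t{more}\n")
    return result


class _null_handle:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False

    def write(self, _):
        pass


def _enzyme_site_length(enzyme_name: str) -> int:
    from .enzymes import builtin_enzymes

    if not enzyme_name:
        return 0
    try:
        return len(builtin_enzymes().get(enzyme_name).recognition)
    except KeyError:
        return 0


def load_truth(path: str | Path) -> dict[str, TruthRow]:
    rows: dict[str, TruthRow] = {}
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for rec in reader:
            row = TruthRow(
                rec["read_id"],
                rec["sample"],
                rec["fragment_id"],
                rec["end"],
                rec["barcode"],
                int(rec["fragment_length"]),
                int(rec["barcode_errors"]),
                int(rec["enzyme_errors"]),
            )
            rows[row.read_id] = row
    return rows


# ---------------------------------------------------------------------------
# evaluation


def percentage(numerator: int, denominator: int) -> float:
    """Percentage rounded to two decimals (the benchmark's table precision)."""
    return round(100.0 * numerator / denominator, 2) if denominator else 0.0


def per_million(numerator: int, denominator: int) -> float:
    return round(1e6 * numerator / denominator, 1) if denominator else 0.0


def per_thousand(numerator: int, denominator: int) -> int:
    return round(1000.0 * numerator / denominator) if denominator else 0


def expected_trimmed_lengths(
    truth: TruthRow,
    config: DemuxConfig,
    enzyme: Enzyme | None,
    read_length: int,
) -> tuple[int, int]:
    """Lengths a perfect trimmer would leave for read 1 and read 2.

    Let F be the fragment length (full sites included), R the recognition
    length, B the barcode length and L the read length.  The pair-resolved
    insert excludes both restriction sites for gbs/rad (F - 2R) and keeps
    them for inline mode (F); each read sees it through its own window
    (read length minus whatever the 5' trim removed), so the expectation is
    min(insert, window).  Single-end rad keeps the trailing site (no pair
    information can remove it).  Assumes the default 5' handling
    (keep_enzyme_5prime adds the retained site back into both terms).
    """
    F = truth.fragment_length
    B = len(truth.barcode)
    L = read_length
    R = len(enzyme.recognition) if enzyme is not None else 0
    if config.mode == "inline":
        return min(F, L - B), min(F, L)
    lead = R if config.keep_enzyme_5prime else 0
    avail1 = L - B - (R - lead)
    avail2 = L - (R - lead)
    insert = F - 2 * R
    if config.mode == "rad" and not config.paired:
        return min(lead + insert + R, avail1), 0
    return min(lead + insert, avail1), min(lead + insert, avail2)


@dataclass
class EvalReport:
    total: int = 0  # simulated units (reads, or pairs counted once)
    assigned: int = 0
    correct: int = 0
    misassigned: int = 0
    undetermined: int = 0
    trim_correct: int = 0

    @property
    def sensitivity_pct(self) -> float:
        return percentage(self.correct, self.total)

    @property
    def misassignments_per_million(self) -> float:
        return per_million(self.misassigned, self.total)

    @property
    def trim_sensitivity_pct(self) -> float:
        return percentage(self.trim_correct, self.correct)

    @property
    def trim_errors_per_thousand(self) -> int:
        return per_thousand(self.correct - self.trim_correct, self.correct)

    def to_tsv(self) -> str:
        lines = [
            f"total_units\t{self.total}",
            f"assigned\t{self.assigned}",
            f"correctly_demultiplexed\t{self.correct}",
            f"misassigned\t{self.misassigned}",
            f"undetermined\t{self.undetermined}",
            f"sensitivity_pct\t{self.sensitivity_pct}",
            f"misassignments_per_million\t{self.misassignments_per_million}",
            f"correctly_trimmed\t{self.trim_correct}",
            f"trimming_sensitivity_pct\t{self.trim_sensitivity_pct}",
            f"trimming_errors_per_thousand\t{self.trim_errors_per_thousand}",
        ]
        return "\n".join(lines) + "\n"


def evaluate_demux(
    truth: dict[str, TruthRow] | str | Path,
    demux_dir: str | Path,
    config: DemuxConfig,
    enzyme: Enzyme | None,
    read_length: int,
    samples: Iterable[str] | None = None,
) -> EvalReport:
    """Score a demultiplexing run against the simulator's ground truth.

    Scans the per-sample FASTQ files in ``demux_dir``.  A unit (read, or
    pair counted once) is *correct* when it was written to its true sample;
    trimming is correct when the read-1 length equals the expectation from
    :func:`expected_trimmed_lengths`.  Read 2 is not scored directly: the
    insert length is read 1's payload, the pair-consistency correction acts
    on it, and read 2 has an intrinsic censoring window (inserts ending
    between the two read windows) that no trimmer can resolve.
    """
    if isinstance(truth, (str, Path)):
        truth = load_truth(truth)
    demux_dir = Path(demux_dir)
    report = EvalReport(total=len(truth))
    if samples is None:
        samples = sorted(
            p.name[: -len(".R1.fastq")]
            for p in demux_dir.glob("*.R1.fastq")
            if not p.name.startswith(UNDETERMINED)
        ) or sorted(
            p.name[: -len(".R1.fastq.gz")]
            for p in demux_dir.glob("*.R1.fastq.gz")
            if not p.name.startswith(UNDETERMINED)
        )
    for sample in samples:
        path1 = _existing(demux_dir, f"{sample}.R1")
        if path1 is None:
            continue
        for rec in read_fastq(path1):
            row = truth.get(rec.id)
            if row is None:
                raise ValueError(f"read {rec.id!r} not present in the truth table")
            report.assigned += 1
            if row.sample != sample:
                report.misassigned += 1
                continue
            report.correct += 1
            exp1, _ = expected_trimmed_lengths(row, config, enzyme, read_length)
            if len(rec) == exp1:
                report.trim_correct += 1
    undet = _existing(demux_dir, f"{UNDETERMINED}.R1")
    if undet is not None:
        report.undetermined = sum(1 for _ in read_fastq(undet))
    return report


def _existing(directory: Path, stem: str) -> Path | None:
    for ext in (".fastq", ".fastq.gz"):
        p = directory / f"{stem}{ext}"
        if p.exists():
            return p
    return None
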