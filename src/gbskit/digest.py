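"""In silico restriction digestion of a reference genome.

Scans each chromosome for recognition-site matches of one or two enzymes
(IUPAC-aware, overlapping matches allowed), converts cut positions into
fragments that tile the chromosome, applies the fragment-size selection that
mirrors a wet-lab gel/bead cut, and reports the statistics a GBS experiment
designer needs: cut counts, fragment counts by flanking-enzyme category, a
fragment-length histogram, and the genomic bases that would actually be
sequenced at a given read length (emitted as BED4 for genome-browser use).
An optional third enzyme can be screened for sites inside retained fragments
(fragments that would be lost in a double-digest protocol).

Fragment boundaries are the top-strand cut positions (recognition match
start + the enzyme's cut offset).  Chromosome-end fragments lack one
restriction end and are therefore reported but never counted as sequencable.
With ``include_full_site`` the sequenced/BED frame of each fragment is
extended outward so both complete recognition sites are included — the
overhang-completion step normally done by editing the BED by hand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .enzymes import IUPAC, Enzyme
from .seqio import BedInterval, FastaRecord, read_fasta, reverse_complement, write_bed

__all__ = [
    "CutSite",
    "Fragment",
    "DigestConfig",
    "DigestReport",
    "CHROM_END",
    "find_cut_sites",
    "find_site_matches",
    "fragments_from_cuts",
    "select_fragments",
    "sequenced_intervals",
    "digest_genome",
]

#: flanking-enzyme label for fragments that touch a chromosome end
CHROM_END = "chrom_end"


@dataclass(frozen=True)
class CutSite:
    chrom: str
    position: int  # bases 5' of the top-strand cut
    enzyme_name: str


@dataclass(frozen=True)
class Fragment:
    """A 0-based half-open inter-cut interval; flanks name the cutting enzymes."""

    chrom: str
    start: int
    end: int
    left_enzyme: str  # enzyme name or CHROM_END
    right_enzyme: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interior(self) -> bool:
        """True iff both flanks are restriction cuts (GBS-sequencable geometry)."""
        return self.left_enzyme != CHROM_END and self.right_enzyme != CHROM_END


@dataclass
class DigestConfig:
    min_fragment: int
    max_fragment: int
    read_length: int = 100
    include_full_site: bool = False
    second_enzyme: Enzyme | None = None
    third_enzyme: Enzyme | None = None
    bin_width: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.min_fragment <= self.max_fragment:
            raise ValueError("need 0 < min_fragment <= max_fragment")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")


@dataclass
class DigestReport:
    """Aggregated digest statistics (totals over all chromosomes)."""

    enzyme_names: list[str]
    cut_counts: dict[str, int] = field(default_factory=dict)
    fragments_total: int = 0
    fragments_by_category: dict[str, int] = field(default_factory=dict)
    fragments_in_range: int = 0
    in_range_by_category: dict[str, int] = field(default_factory=dict)
    length_histogram: dict[int, int] = field(default_factory=dict)
    sequenced_bases: int = 0
    third_enzyme_name: str | None = None
    fragments_with_third_site: int | None = None
    genome_length: int = 0
    chromosomes: int = 0

    def to_tsv(self) -> str:
        lines = [
            f"chromosomes\t{self.chromosomes}",
            f"genome_length\t{self.genome_length}",
        ]
        for name in self.enzyme_names:
            lines.append(f"cut_sites\t{name}\t{self.cut_counts.get(name, 0)}")
        lines.append(f"fragments_total\t{self.fragments_total}")
        for cat in sorted(self.fragments_by_category):
            lines.append(f"fragments\t{cat}\t{self.fragments_by_category[cat]}")
        lines.append(f"fragments_in_range\t{self.fragments_in_range}")
        for cat in sorted(self.in_range_by_category):
            lines.append(f"fragments_in_range\t{cat}\t{self.in_range_by_category[cat]}")
        lines.append(f"predicted_sequenced_bases\t{self.sequenced_bases}")
        if self.fragments_with_third_site is not None:
            lines.append(
                f"fragments_with_{self.third_enzyme_name}_site\t"
                f"{self.fragments_with_third_site}"
            )
        lines.append("length_histogram\tbin_start\tcount")
        for b in sorted(self.length_histogram):
            lines.append(f"length_histogram\t{b}\t{self.length_histogram[b]}")
        return "\n".join(lines) + "\n"


def _pattern_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC pattern into an overlapping-match regex."""
    parts = []
    for code in pattern:
        bases = sorted(IUPAC[code])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile(r"(?=(" + "".join(parts) + r"))")


def _is_degenerate_palindrome(pattern: str) -> bool:
    """True iff a pattern equals its own reverse complement at the IUPAC level."""
    rc = reverse_complement(pattern)
    return all(IUPAC[a] == IUPAC[b] for a, b in zip(pattern, rc))


def find_site_matches(sequence: str, enzyme: Enzyme) -> list[int]:
    """Start positions of top-strand recognition matches (overlaps allowed)."""
    regex = _pattern_regex(enzyme.recognition)
    return [m.start() for m in regex.finditer(sequence)]


def find_cut_sites(record: FastaRecord, enzyme: Enzyme) -> list[CutSite]:
    """All top-strand cut positions of ``enzyme`` on a chromosome.

    Degenerate-palindromic recognition sequences (e.g. ApeKI's GCWGC) need a
    single scan; otherwise the reverse-complement pattern is scanned too and
    the cut position of a bottom-strand match is mapped back onto the top
    strand.  Cut positions are deduplicated and sorted.
    """
    seq = record.sequence
    positions = {
        m + enzyme.cut_offset for m in find_site_matches(seq, enzyme)
    }
    if not _is_degenerate_palindrome(enzyme.recognition):
        rc_pattern = reverse_complement(enzyme.recognition)
        rc_offset = len(enzyme.recognition) - enzyme.cut_offset
        regex = _pattern_regex(rc_pattern)
        positions.update(m.start() + rc_offset for m in regex.finditer(seq))
    return [
        CutSite(record.id, pos, enzyme.name)
        for pos in sorted(positions)
        if 0 <= pos <= len(seq)
    ]


def fragments_from_cuts(
    chrom: str, seq_length: int, cuts: Iterable[CutSite]
) -> list[Fragment]:
    """Tile a chromosome into inter-cut fragments.

    Cuts must be sorted by position.  Zero-length end fragments (cut exactly
    at a chromosome boundary) are dropped; the remaining fragments partition
    [0, seq_length) exactly.
    """
    fragments: list[Fragment] = []
    prev_pos = 0
    prev_enz = CHROM_END
    for cut in cuts:
        if cut.position > prev_pos:
            fragments.append(
                Fragment(chrom, prev_pos, cut.position, prev_enz, cut.enzyme_name)
            )
        prev_pos, prev_enz = cut.position, cut.enzyme_name
    if seq_length > prev_pos:
        fragments.append(Fragment(chrom, prev_pos, seq_length, prev_enz, CHROM_END))
    return fragments


def _category(frag: Fragment) -> str:
    if not frag.interior:
        return CHROM_END
    return "-".join(sorted((frag.left_enzyme, frag.right_enzyme)))


def select_fragments(fragments: Iterable[Fragment], config: DigestConfig) -> list[Fragment]:
    """Interior fragments within the inclusive size range."""
    return [
        f
        for f in fragments
        if f.interior and config.min_fragment <= f.length <= config.max_fragment
    ]


def sequenced_intervals(
    fragment: Fragment,
    read_length: int,
    include_full_site: bool = False,
    enzymes_by_name: dict[str, Enzyme] | None = None,
    chrom_length: int | None = None,
) -> list[BedInterval]:
    """Predicted sequenced bases of one fragment (1 or 2 BED intervals).

    Reads start at both restriction ends; the two read intervals are merged
    when they overlap.  With ``include_full_site`` the fragment frame is first
    extended so each flanking recognition site is fully included: left by the
    left enzyme's cut offset, right by (site length - cut offset) of the right
    enzyme, clamped to the chromosome.
    """
    start, end = fragment.start, fragment.end
    if include_full_site:
        if enzymes_by_name is None:
            raise ValueError("include_full_site requires the enzyme definitions")
        left = enzymes_by_name[fragment.left_enzyme]
        right = enzymes_by_name[fragment.right_enzyme]
        start = max(0, start - left.cut_offset)
        end = end + (len(right.recognition) - right.cut_offset)
        if chrom_length is not None:
            end = min(end, chrom_length)
    name = f"{fragment.chrom}_{fragment.start}_{fragment.end}"
    fwd_end = min(start + read_length, end)
    rev_start = max(end - read_length, start)
    if rev_start <= fwd_end:  # reads overlap -> single merged interval
        return [BedInterval(fragment.chrom, start, end, name)]
    return [
        BedInterval(fragment.chrom, start, fwd_end, name + "_fwd"),
        BedInterval(fragment.chrom, rev_start, end, name + "_rev"),
    ]


def _merged_length(intervals: list[BedInterval]) -> int:
    """Total genomic bases covered by intervals (union, per chromosome)."""
    total = 0
    by_chrom: dict[str, list[BedInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = iv.start, iv.end
            else:
                cur_e = max(cur_e, iv.end)
        total += cur_e - cur_s
    return total


def digest_genome(
    fasta_path: str | Path,
    enzyme: Enzyme,
    config: DigestConfig,
    bed_path: str | Path | None = None,
) -> DigestReport:
    """Digest a (multi-contig) FASTA and collect the full report.

    With ``config.second_enzyme`` the cut sets of both enzymes are merged
    before fragmentation; with ``config.third_enzyme`` retained fragments are
    additionally screened for internal third-enzyme sites (matches entirely
    within the fragment interval).
    """
    enzymes = [enzyme] + ([config.second_enzyme] if config.second_enzyme else [])
    enzymes_by_name = {e.name: e for e in enzymes}
    report = DigestReport(enzyme_names=[e.name for e in enzymes])
    report.cut_counts = {e.name: 0 for e in enzymes}
    if config.third_enzyme is not None:
        report.third_enzyme_name = config.third_enzyme.name
        report.fragments_with_third_site = 0

    bed_intervals: list[BedInterval] = []
    for record in read_fasta(fasta_path):
        report.chromosomes += 1
        report.genome_length += len(record)
        cuts: list[CutSite] = []
        for enz in enzymes:
            enz_cuts = find_cut_sites(record, enz)
            report.cut_counts[enz.name] += len(enz_cuts)
            cuts.extend(enz_cuts)
        cuts.sort(key=lambda c: (c.position, c.enzyme_name))
        fragments = fragments_from_cuts(record.id, len(record), cuts)
        for frag in fragments:
            report.fragments_total += 1
            cat = _category(frag)
            report.fragments_by_category[cat] = (
                report.fragments_by_category.get(cat, 0) + 1
            )
            b = (frag.length // config.bin_width) * config.bin_width
            report.length_histogram[b] = report.length_histogram.get(b, 0) + 1
        retained = select_fragments(fragments, config)
        for frag in retained:
            report.fragments_in_range += 1
            cat = _category(frag)
            report.in_range_by_category[cat] = (
                report.in_range_by_category.get(cat, 0) + 1
            )
            bed_intervals.extend(
                sequenced_intervals(
                    frag,
                    config.read_length,
                    config.include_full_site,
                    enzymes_by_name,
                    len(record),
                )
            )
            if config.third_enzyme is not None:
                sub = record.sequence[frag.start : frag.end]
                matches = find_site_matches(sub, config.third_enzyme)
                if not matches and not _is_degenerate_palindrome(
                    config.third_enzyme.recognition
                ):
                    rc = reverse_complement(config.third_enzyme.recognition)
                    matches = [m.start() for m in _pattern_regex(rc).finditer(sub)]
                if matches:
                    report.fragments_with_third_site += 1
    if report.chromosomes == 0:
        raise ValueError(f"{fasta_path}: empty FASTA")
    report.sequenced_bases = _merged_length(bed_intervals) if bed_intervals else 0
    if bed_path is not None:
        write_bed(bed_intervals, bed_path)
    return report
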