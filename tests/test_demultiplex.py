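import pytest

from gbskit.demultiplex import (
    DemuxConfig,
    SampleRow,
    SampleSheet,
    SampleSheetError,
    UNDETERMINED,
    demultiplex_run,
    match_read,
    reconcile_pair,
    trim_3prime_read1,
    trim_3prime_read2,
    trim_5prime,
)
from gbskit.barcodes import generate_barcodes
from gbskit.seqio import ReadRecord, read_fastq, reverse_complement
from gbskit.simulate import DEFAULT_ADAPTER, SimConfig, random_fragment_set, simulate_reads

ADAPTER = DEFAULT_ADAPTER  # AGATCGGAAGAGCG


def _read(seq, rid="r"):
    return ReadRecord(rid, seq, "I" * len(seq))


@pytest.fixture()
def sheet():
    return SampleSheet([SampleRow("S1", "ACGTACGT", "ApeKI")])


@pytest.fixture()
def gbs_config():
    return DemuxConfig(mode="gbs", common_adapter=ADAPTER)


class TestMatching:
    def test_exact_match(self, sheet, gbs_config, enzyme_table):
        read = _read("ACGTACGT" + "GCAGC" + "T" * 40)
        m = match_read(read, sheet, gbs_config, enzyme_table)
        assert (m.sample, m.barcode_mismatches, m.enzyme_mismatches) == ("S1", 0, 0)
        assert m.prefix_length == 13

    def test_one_barcode_mismatch(self, sheet, gbs_config, enzyme_table):
        m = match_read(
            _read("ACGAACGT" + "GCAGC" + "T" * 40), sheet, gbs_config, enzyme_table
        )
        assert (m.sample, m.barcode_mismatches) == ("S1", 1)

    def test_two_mismatches_undetermined(self, sheet, gbs_config, enzyme_table):
        m = match_read(
            _read("ACGAACGA" + "GCAGC" + "T" * 40), sheet, gbs_config, enzyme_table
        )
        assert not m.assigned

    def test_enzyme_mismatch_budget(self, sheet, gbs_config, enzyme_table):
        one = match_read(
            _read("ACGTACGT" + "GCACC" + "T" * 40), sheet, gbs_config, enzyme_table
        )
        assert (one.sample, one.enzyme_mismatches) == ("S1", 1)
        two = match_read(
            _read("ACGTACGT" + "TCACC" + "T" * 40), sheet, gbs_config, enzyme_table
        )
        assert not two.assigned

    def test_short_read_undetermined(self, sheet, gbs_config, enzyme_table):
        assert not match_read(_read("ACGTAC"), sheet, gbs_config, enzyme_table).assigned

    def test_inline_mode_ignores_enzyme(self, enzyme_table):
        sheet = SampleSheet([SampleRow("S1", "ACGTACGT", "")])
        config = DemuxConfig(mode="inline")
        m = match_read(_read("ACGTACGT" + "TTTTT" + "T" * 20), sheet, config)
        assert m.assigned and m.prefix_length == 8

    def test_true_tie_is_undetermined(self, enzyme_table):
        sheet = SampleSheet(
            [SampleRow("A", "AAAATTTT", "ApeKI"), SampleRow("B", "AAAATTTA", "ApeKI")]
        )
        config = DemuxConfig(mode="gbs")
        # one mismatch against each barcode: a true tie
        m = match_read(
            _read("AAAATTTG" + "GCAGC" + "T" * 30), sheet, config, enzyme_table
        )
        assert not m.assigned

    def test_longer_barcode_wins_equal_mismatches(self, enzyme_table):
        # not prefixes of each other; read matches both exactly up to their length
        sheet = SampleSheet(
            [SampleRow("short", "AAAACCCC", "ApeKI"),
             SampleRow("long", "AAAACCCCA", "ApeKI")]
        )
        config = DemuxConfig(mode="gbs")
        # read carries the long barcode followed by a perfect site: the short
        # probe sees site bases at its enzyme offset and mismatches out
        read = _read("AAAACCCCA" + "GCAGC" + "T" * 30)
        m = match_read(read, sheet, config, enzyme_table)
        assert m.sample == "long"

    def test_inline_longest_barcode_tiebreak(self):
        # without an enzyme a barcode may extend another; the longer match wins
        sheet = SampleSheet(
            [SampleRow("short", "AAAATTTT", ""), SampleRow("long", "AAAATTTTGCAG", "")]
        )
        config = DemuxConfig(mode="inline")
        m = match_read(_read("AAAATTTTGCAG" + "T" * 20), sheet, config)
        assert m.sample == "long"

    def test_keep_enzyme_5prime_prefix(self, sheet, enzyme_table):
        config = DemuxConfig(mode="gbs", keep_enzyme_5prime=True)
        m = match_read(
            _read("ACGTACGT" + "GCAGC" + "T" * 40), sheet, config, enzyme_table
        )
        assert m.prefix_length == 8


class TestTrimming:
    def test_trim_5prime(self, sheet, gbs_config, enzyme_table):
        read = _read("ACGTACGT" + "GCAGC" + "T" * 87)
        m = match_read(read, sheet, gbs_config, enzyme_table)
        trimmed = trim_5prime(read, m)
        assert len(trimmed) == 87
        assert trimmed.sequence == "T" * 87
        assert trimmed.quality == "I" * 87

    def test_trim_3prime_gbs_site_plus_partial_adapter(self, apeki, gbs_config):
        read = _read("TTTTACGT" + "GCTGC" + "AGATCGGA")
        out, trimmed = trim_3prime_read1(read, apeki, gbs_config)
        assert trimmed and out.sequence == "TTTTACGT"

    def test_trim_3prime_gbs_no_site(self, apeki, gbs_config):
        read = _read("TTTTACGTTTTTACGTAAAA")
        out, trimmed = trim_3prime_read1(read, apeki, gbs_config)
        assert not trimmed and out.sequence == read.sequence

    def test_trim_3prime_gbs_adapter_mismatch_negative_control(self, apeki, gbs_config):
        # site present but followed by non-adapter sequence
        read = _read("TTTTACGT" + "GCTGC" + "CCCCCCCC" + "TT")
        out, trimmed = trim_3prime_read1(read, apeki, gbs_config)
        assert not trimmed

    def test_trim_3prime_gbs_flush_site(self, apeki, gbs_config):
        # site ending exactly at the read end trims with zero adapter bases
        read = _read("TTTTACGTTT" + "GCAGC")
        out, trimmed = trim_3prime_read1(read, apeki, gbs_config)
        assert trimmed and out.sequence == "TTTTACGTTT"

    def test_trim_3prime_rad_adapter_only(self, apeki):
        config = DemuxConfig(mode="rad", common_adapter=ADAPTER)
        read = _read("TTTTACGTGCTGC" + ADAPTER[:6])
        out, trimmed = trim_3prime_read1(read, apeki, config)
        assert trimmed and out.sequence == "TTTTACGTGCTGC"
        # fewer than 3 adapter bases at the end: not trimmed
        short = _read("TTTTACGTGCTGC" + ADAPTER[:2])
        out2, trimmed2 = trim_3prime_read1(short, apeki, config)
        assert not trimmed2

    def test_trim_3prime_read2_site_plus_barcode(self, apeki, gbs_config):
        barcode = "ACGTACGT"
        read2 = _read("TTACGTAAAA" + "GCTGC" + reverse_complement(barcode) + "AGAT")
        out, trimmed = trim_3prime_read2(read2, apeki, barcode, gbs_config)
        assert trimmed and out.sequence == "TTACGTAAAA"

    def test_trim_3prime_read2_tolerates_one_substitution(self, apeki, gbs_config):
        barcode = "ACGTACGT"
        rc = reverse_complement(barcode)
        mutated = "G" + rc[1:] if rc[0] != "G" else "C" + rc[1:]
        read2 = _read("TTACGTAAAA" + "GCTGC" + mutated)
        out, trimmed = trim_3prime_read2(read2, apeki, barcode, gbs_config)
        assert trimmed and out.sequence == "TTACGTAAAA"

    def test_trim_3prime_read2_long_insert_unchanged(self, apeki, gbs_config):
        read2 = _read("TTACGTAAAATTACGTAAAA")
        out, trimmed = trim_3prime_read2(read2, apeki, "ACGTACGT", gbs_config)
        assert not trimmed


class TestReconcile:
    def _pair(self, insert):
        """Build a trimmed/untrimmed pair from one synthetic insert."""
        r1 = _read(insert, "p")  # correctly trimmed to the insert
        # read 2 missed its trim: revcomp(insert) plus read-through bases
        r2_full = reverse_complement(insert) + "GCAGC" + "TTTTTTTT" + "A"
        return r1, _read(r2_full, "p")

    def test_overlap_match_trims_longest(self, apeki, gbs_config):
        insert = "ACCTGAGATT"
        r1, r2 = self._pair(insert)
        out1, out2 = reconcile_pair(r1, r2, r1, r2, apeki, 8, gbs_config)
        assert out1.sequence == insert
        assert out2.sequence == reverse_complement(insert)

    def test_equal_lengths_untouched(self, apeki, gbs_config):
        r1, r2 = _read("ACGTACGT"), _read("TTTTACGT")
        assert reconcile_pair(r1, r2, r1, r2, apeki, 8, gbs_config) == (r1, r2)

    def test_overlap_mismatch_restores_short_from_original(self, apeki, gbs_config):
        # read 1 was over-trimmed by a spurious internal site; read 2 is right
        original1 = _read("ACCTGAGATTCCGGAAT", "p")
        overtrimmed1 = original1.slice(0, 5)
        r2 = _read(reverse_complement("ACCTGAGATTCCGGAAT"), "p")
        out1, out2 = reconcile_pair(
            overtrimmed1, r2, original1, r2, apeki, 8, gbs_config
        )
        assert out1.sequence == original1.sequence[: len(r2)]
        assert out2 == r2


def _simulate(tmp_path, apeki, n_samples=6, n_frags=40, error_rate=0.0,
              paired=True, seed=5):
    bset = generate_barcodes(n_samples, apeki, 8, 16, seed=seed)
    frags = random_fragment_set(n_frags, apeki, 60, 90, seed=seed + 1)
    config = SimConfig(read_length=100, reads_per_locus=2, paired=paired,
                       error_rate=error_rate, seed=seed + 2)
    result = simulate_reads(
        frags, [(s, "ApeKI") for s in bset.sequences()], config, tmp_path / "sim"
    )
    sheet = SampleSheet(
        [SampleRow(f"S{i + 1:02d}", s, "ApeKI") for i, s in enumerate(bset.sequences())]
    )
    return result, sheet


class TestDemultiplexRun:
    def test_zero_noise_full_recovery(self, tmp_path, apeki, enzyme_table):
        result, sheet = _simulate(tmp_path, apeki)
        config = DemuxConfig(mode="gbs", common_adapter=ADAPTER, paired=True)
        stats = demultiplex_run(
            result.fastq1, result.fastq2, sheet, config, tmp_path / "out",
            enzyme_table=enzyme_table,
        )
        assert stats.undetermined == 0
        assert stats.assigned() == result.reads
        # every read landed in its true sample
        for row in sheet.rows:
            for rec in read_fastq(tmp_path / "out" / f"{row.sample}.R1.fastq"):
                assert rec.id.startswith(row.sample + ":")

    def test_read_conservation_with_errors(self, tmp_path, apeki, enzyme_table):
        result, sheet = _simulate(tmp_path, apeki, error_rate=0.05)
        config = DemuxConfig(mode="gbs", common_adapter=ADAPTER, paired=True)
        stats = demultiplex_run(
            result.fastq1, result.fastq2, sheet, config, tmp_path / "out",
            enzyme_table=enzyme_table,
        )
        per_sample = sum(s.reads for s in stats.per_sample.values())
        assert per_sample + stats.undetermined == stats.total == result.reads

    def test_mismatch_histogram_matches_simulator_truth(
        self, tmp_path, apeki, enzyme_table
    ):
        result, sheet = _simulate(tmp_path, apeki, error_rate=0.02)
        config = DemuxConfig(mode="gbs", common_adapter=ADAPTER, paired=True)
        stats = demultiplex_run(
            result.fastq1, result.fastq2, sheet, config, tmp_path / "out",
            enzyme_table=enzyme_table,
        )
        hist = {}
        for s in stats.per_sample.values():
            for mm, n in s.mismatch_counts.items():
                hist[mm] = hist.get(mm, 0) + n
        # assigned mismatch-0/1 counts cannot exceed the simulated error
        # histogram, and must account for almost all such reads
        truth_hist = result.barcode_error_histogram
        assert hist.get(0, 0) <= truth_hist.get(0, 0)
        assert hist.get(0, 0) >= truth_hist.get(0, 0) * 0.99
        assert hist.get(1, 0) <= truth_hist.get(1, 0)

    def test_more_mismatch_budget_never_loses_reads(
        self, tmp_path, apeki, enzyme_table
    ):
        result, sheet = _simulate(tmp_path, apeki, error_rate=0.03)
        counts = []
        for budget in (0, 1, 2):
            config = DemuxConfig(
                mode="gbs", common_adapter=ADAPTER,
                barcode_mismatches=budget, paired=True,
            )
            stats = demultiplex_run(
                result.fastq1, result.fastq2, sheet, config,
                tmp_path / f"out{budget}", enzyme_table=enzyme_table,
            )
            counts.append(stats.assigned())
        assert counts == sorted(counts)

    def test_gbs_and_rad_assign_identically(self, tmp_path, apeki, enzyme_table):
        result, sheet = _simulate(tmp_path, apeki, error_rate=0.02)
        assignments = {}
        for mode in ("gbs", "rad"):
            config = DemuxConfig(mode=mode, common_adapter=ADAPTER, paired=True)
            demultiplex_run(
                result.fastq1, result.fastq2, sheet, config,
                tmp_path / mode, enzyme_table=enzyme_table,
            )
            assignments[mode] = {
                row.sample: sorted(
                    r.id for r in read_fastq(tmp_path / mode / f"{row.sample}.R1.fastq")
                )
                for row in sheet.rows
            }
        assert assignments["gbs"] == assignments["rad"]

    def test_single_end_assigns_same_reads_as_paired(
        self, tmp_path, apeki, enzyme_table
    ):
        result, sheet = _simulate(tmp_path, apeki, error_rate=0.02)
        config_p = DemuxConfig(mode="gbs", common_adapter=ADAPTER, paired=True)
        demultiplex_run(result.fastq1, result.fastq2, sheet, config_p,
                        tmp_path / "p", enzyme_table=enzyme_table)
        config_s = DemuxConfig(mode="gbs", common_adapter=ADAPTER, paired=False)
        demultiplex_run(result.fastq1, None, sheet, config_s,
                        tmp_path / "s", enzyme_table=enzyme_table)
        for row in sheet.rows:
            ids_p = {r.id for r in read_fastq(tmp_path / "p" / f"{row.sample}.R1.fastq")}
            ids_s = {r.id for r in read_fastq(tmp_path / "s" / f"{row.sample}.R1.fastq")}
            assert ids_p == ids_s

    def test_undetermined_written_untrimmed(self, tmp_path, apeki, enzyme_table):
        result, sheet = _simulate(tmp_path, apeki, n_samples=3)
        # a sheet with an unrelated barcode sends everything to undetermined
        decoy = SampleSheet([SampleRow("X", "CCCCCCGGGGGG", "ApeKI")])
        config = DemuxConfig(mode="gbs", common_adapter=ADAPTER, paired=True)
        stats = demultiplex_run(
            result.fastq1, result.fastq2, decoy, config, tmp_path / "out",
            enzyme_table=enzyme_table,
        )
        assert stats.undetermined == stats.total
        undet = list(read_fastq(tmp_path / "out" / f"{UNDETERMINED}.R1.fastq"))
        assert all(len(r) == 100 for r in undet)

    def test_unequal_paired_files_error(self, tmp_path, apeki, enzyme_table):
        result, sheet = _simulate(tmp_path, apeki, n_samples=2, n_frags=5)
        short = tmp_path / "short.fastq"
        lines = result.fastq2.read_text().splitlines()[:-4]
        short.write_text("\n".join(lines) + "\n")
        config = DemuxConfig(mode="gbs", common_adapter=ADAPTER, paired=True)
        with pytest.raises(ValueError, match="unequal"):
            demultiplex_run(result.fastq1, short, sheet, config,
                            tmp_path / "out", enzyme_table=enzyme_table)

    def test_unknown_enzyme_error(self, tmp_path, apeki, enzyme_table):
        result, _ = _simulate(tmp_path, apeki, n_samples=2, n_frags=5)
        sheet = SampleSheet([SampleRow("S1", "ACGTACGT", "NotAnEnzyme")])
        config = DemuxConfig(mode="gbs")
        with pytest.raises(KeyError, match="NotAnEnzyme"):
            demultiplex_run(result.fastq1, None, sheet, config,
                            tmp_path / "out", enzyme_table=enzyme_table)

    def test_stats_file_written(self, tmp_path, apeki, enzyme_table):
        result, sheet = _simulate(tmp_path, apeki, n_samples=2, n_frags=5)
        config = DemuxConfig(mode="gbs", common_adapter=ADAPTER, paired=True)
        demultiplex_run(result.fastq1, result.fastq2, sheet, config,
                        tmp_path / "out", enzyme_table=enzyme_table)
        text = (tmp_path / "out" / "demux_stats.tsv").read_text()
        assert text.startswith("sample\treads\tpercent")
        assert UNDETERMINED in text


def test_sheet_validation():
    with pytest.raises(SampleSheetError):
        SampleSheet([SampleRow("A", "ACGT", ""), SampleRow("A", "TTTT", "")])
    with pytest.raises(SampleSheetError):
        SampleSheet([SampleRow("A", "ACGT", ""), SampleRow("B", "ACGT", "")])
    with pytest.raises(SampleSheetError):
        SampleSheet([SampleRow("A", "ACGN", "")])


def test_sheet_from_file(tmp_path):
    p = tmp_path / "sheet.tsv"
    p.write_text("# sample\tbarcode\tenzyme\nS1\tacgtacgt\tApeKI\nS2\tTTTTCCCC\n")
    sheet = SampleSheet.from_file(p)
    assert sheet.rows[0] == SampleRow("S1", "ACGTACGT", "ApeKI")
    assert sheet.rows[1].enzyme_name == ""
    assert sheet.max_barcode_length() == 8
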