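"""Read extraction: flag filtering, pairing, mate rescue, FASTQ round trip."""

import pysam
import pytest

from remapfix.extract import (
    EXCLUDE_FLAGS,
    ExtractionStats,
    ReadPair,
    fastq_to_pairs,
    pair_and_dedup,
    pairs_to_fastq,
    revcomp,
    select_alignments,
)
from remapfix.intervals import GenomicInterval


def iv(contig, start, end):
    return GenomicInterval(contig, start, end)


CONTIGS = {"chrA": 10_000, "chrB": 10_000}


def pair_records(name, pos1, pos2, contig="chrA", flags=(99, 147), **extra):
    length = 100
    return [
        dict(
            name=name, flag=flags[0], contig=contig, pos=pos1, cigar=f"{length}M",
            next_contig=contig, next_pos=pos2, **extra,
        ),
        dict(
            name=name, flag=flags[1], contig=contig, pos=pos2, cigar=f"{length}M",
            next_contig=contig, next_pos=pos1, **extra,
        ),
    ]


class TestSelectAlignments:
    def test_flag_mask_is_2316(self):
        assert EXCLUDE_FLAGS == 2316

    def test_excludes_masked_flags_keeps_dup_and_qcfail(self, tmp_bam_factory):
        records = [
            dict(name="ok", flag=99, contig="chrA", pos=500, cigar="100M",
                 next_contig="chrA", next_pos=700),
            dict(name="supp", flag=99 | 0x800, contig="chrA", pos=500,
                 cigar="100M", next_contig="chrA", next_pos=700),
            dict(name="sec", flag=99 | 0x100, contig="chrA", pos=500,
                 cigar="100M", next_contig="chrA", next_pos=700),
            dict(name="mate_unmapped", flag=99 | 0x8, contig="chrA", pos=500,
                 cigar="100M", next_contig="chrA", next_pos=700),
            dict(name="dupfl", flag=99 | 0x400, contig="chrA", pos=500,
                 cigar="100M", next_contig="chrA", next_pos=700),
            dict(name="qcfail", flag=99 | 0x200, contig="chrA", pos=500,
                 cigar="100M", next_contig="chrA", next_pos=700),
        ]
        bam = tmp_bam_factory(CONTIGS, records)
        got = {r.query_name for r in select_alignments(bam, [iv("chrA", 0, 1000)])}
        assert got == {"ok", "dupfl", "qcfail"}

    def test_overlapping_intervals_report_record_once(self, tmp_bam_factory):
        bam = tmp_bam_factory(CONTIGS, pair_records("p1", 450, 800))
        got = select_alignments(bam, [iv("chrA", 0, 500), iv("chrA", 400, 900)])
        assert len(got) == 2  # both mates, each exactly once

    def test_matches_linear_scan_oracle(self, tmp_bam_factory):
        records = []
        for i, (pos, flag) in enumerate(
            [(100, 99), (250, 147), (600, 99 | 0x800), (900, 0x4 | 0x1 | 0x40),
             (1300, 99), (1500, 99 | 0x100), (2200, 147), (2500, 99),
             (3000, 147), (4000, 99), (5000, 99 | 0x200), (8000, 99)]
        ):
            records.append(
                dict(name=f"r{i}", flag=flag, contig="chrA",
                     pos=pos, cigar="100M", next_contig="chrA", next_pos=pos + 200)
            )
        bam = tmp_bam_factory(CONTIGS, records)
        intervals = [iv("chrA", 200, 1400), iv("chrA", 1200, 3100)]
        got = {
            (r.query_name, r.flag) for r in select_alignments(bam, intervals)
        }
        oracle = set()
        with pysam.AlignmentFile(bam) as aln:
            for rec in aln.fetch(until_eof=True):
                if rec.flag & EXCLUDE_FLAGS:
                    continue
                if any(
                    rec.reference_start < i.end and rec.reference_end > i.start
                    for i in intervals
                ):
                    oracle.add((rec.query_name, rec.flag))
        assert got == oracle

    def test_unindexed_input_instructs_to_index(self, tmp_bam_factory, tmp_path):
        bam = tmp_bam_factory(CONTIGS, pair_records("p1", 100, 300))
        import os
        os.remove(bam + ".bai")
        with pytest.raises(FileNotFoundError, match="index"):
            select_alignments(bam, [iv("chrA", 0, 1000)])

    def test_missing_contig_skipped_with_warning(self, tmp_bam_factory):
        bam = tmp_bam_factory(CONTIGS, pair_records("p1", 100, 300))
        stats = ExtractionStats()
        got = select_alignments(
            bam, [iv("chrZ", 0, 100), iv("chrA", 0, 1000)], stats
        )
        assert len(got) == 2
        assert stats.skipped_contigs == ["chrZ"]


class TestPairAndDedup:
    def test_both_mates_selected_orientation_restored(self, tmp_bam_factory):
        seq_fwd = "ACGT" * 25
        seq_rev_stored = "TTTT" + "ACGT" * 24
        records = [
            dict(name="p1", flag=99, contig="chrA", pos=100, cigar="100M",
                 seq=seq_fwd, next_contig="chrA", next_pos=300),
            dict(name="p1", flag=147, contig="chrA", pos=300, cigar="100M",
                 seq=seq_rev_stored, next_contig="chrA", next_pos=100),
        ]
        bam = tmp_bam_factory(CONTIGS, records)
        pairs = pair_and_dedup(select_alignments(bam, [iv("chrA", 0, 1000)]), bam)
        assert len(pairs) == 1
        assert pairs[0].mate1[0] == seq_fwd
        # reverse-strand mate is flipped back to sequencer orientation
        assert pairs[0].mate2[0] == revcomp(seq_rev_stored)

    def test_mate_rescued_within_window(self, tmp_bam_factory):
        records = [
            dict(name="p1", flag=99, contig="chrA", pos=900, cigar="100M",
                 next_contig="chrA", next_pos=1400),
            dict(name="p1", flag=147, contig="chrA", pos=1400, cigar="100M",
                 next_contig="chrA", next_pos=900),
        ]
        bam = tmp_bam_factory(CONTIGS, records)
        selected = select_alignments(bam, [iv("chrA", 0, 1000)])
        assert len(selected) == 1  # mate lies outside the fetched interval
        stats = ExtractionStats()
        pairs = pair_and_dedup(selected, bam, rescue_window=1000, stats=stats)
        assert len(pairs) == 1
        assert stats.pairs_rescued == 1

    def test_unrescued_singleton_dropped(self, tmp_bam_factory):
        records = [
            dict(name="p1", flag=99, contig="chrA", pos=900, cigar="100M",
                 next_contig="chrA", next_pos=5000),
            dict(name="p1", flag=147, contig="chrA", pos=5000, cigar="100M",
                 next_contig="chrA", next_pos=900),
        ]
        bam = tmp_bam_factory(CONTIGS, records)
        selected = select_alignments(bam, [iv("chrA", 0, 1000)])
        stats = ExtractionStats()
        pairs = pair_and_dedup(selected, bam, rescue_window=1000, stats=stats)
        assert pairs == []
        assert stats.dropped_singletons == 1

    def test_duplicate_mate1_name_dropped(self, tmp_bam_factory):
        records = [
            dict(name="p1", flag=99, contig="chrA", pos=100, cigar="100M",
                 next_contig="chrA", next_pos=300),
            dict(name="p1", flag=99, contig="chrA", pos=200, cigar="100M",
                 next_contig="chrA", next_pos=300),
        ]
        bam = tmp_bam_factory(CONTIGS, records)
        stats = ExtractionStats()
        pairs = pair_and_dedup(
            select_alignments(bam, [iv("chrA", 0, 1000)]), bam, stats=stats
        )
        assert pairs == []
        assert stats.dropped_ambiguous == 1

    def test_read_group_carried(self, tmp_bam_factory):
        records = pair_records("p1", 100, 300)
        for r in records:
            r["tags"] = [("RG", "rg7")]
        bam = tmp_bam_factory(CONTIGS, records)
        pairs = pair_and_dedup(select_alignments(bam, [iv("chrA", 0, 1000)]), bam)
        assert pairs[0].read_group == "rg7"


class TestFastq:
    def test_empty_input_empty_streams(self, tmp_path):
        f1, f2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        pairs_to_fastq([], f1, f2)
        assert f1.read_text() == "" and f2.read_text() == ""

    def test_round_trip_byte_identical(self, tmp_path):
        pairs = [
            ReadPair(f"read{i}", ("ACGTAC", "IIIIII"), ("GGGTTT", "IIIHHH"))
            for i in range(3)
        ]
        f1, f2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        pairs_to_fastq(pairs, f1, f2)
        text1, text2 = f1.read_text(), f2.read_text()
        back = fastq_to_pairs(f1, f2)
        assert [p.name for p in back] == [p.name for p in pairs]
        pairs_to_fastq(back, f1, f2)
        assert f1.read_text() == text1 and f2.read_text() == text2

    def test_quality_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ReadPair("x", ("ACGT", "II"), ("ACGT", "IIII"))
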