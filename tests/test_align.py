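"""Builtin mapper, pair placement, external backend, and splice-back."""

import random

import pysam
import pytest

from remapfix.align import (
    BackendError,
    BuiltinParams,
    ExternalBackend,
    ReferenceIndex,
    align_pairs,
    builtin_map_read,
    pair_rescue,
    splice_back,
)
from remapfix.extract import ReadPair, revcomp
from remapfix.refpatch import ReferenceSequenceSet

from .conftest import make_bam, random_sequence


@pytest.fixture(scope="module")
def unique_ref():
    rng = random.Random(42)
    return ReferenceSequenceSet([("chr1", random_sequence(rng, 5000))])


@pytest.fixture(scope="module")
def unique_index(unique_ref):
    return ReferenceIndex(unique_ref, BuiltinParams())


def exhaustive_best(ref: ReferenceSequenceSet, read: str):
    """Oracle: score the read at every offset of every contig and strand."""
    best = []
    for ci, (name, seq) in enumerate(ref.contigs):
        for strand, s in ((0, read), (1, revcomp(read))):
            for off in range(len(seq) - len(s) + 1):
                mm = sum(1 for a, b in zip(seq[off : off + len(s)], s) if a != b)
                score = (len(s) - mm) - 4 * mm
                best.append((score, ci, off, strand))
    best.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    return best


class TestBuiltinMapRead:
    def test_exact_unique_read_maps_with_mapq60(self, unique_ref, unique_index):
        read = unique_ref.sequence("chr1")[1000:1100]
        placement = builtin_map_read(read, unique_index)
        assert placement.pos == 1000
        assert placement.strand == 0
        assert placement.score == 100
        assert placement.mapq == 60
        assert placement.mismatches == 0

    def test_reverse_strand_read_found(self, unique_ref, unique_index):
        read = revcomp(unique_ref.sequence("chr1")[2000:2100])
        placement = builtin_map_read(read, unique_index)
        assert placement.pos == 2000 and placement.strand == 1

    def test_two_identical_loci_tie_gives_mapq0(self):
        rng = random.Random(7)
        core = random_sequence(rng, 300)
        ref = ReferenceSequenceSet(
            [("c1", random_sequence(rng, 200) + core + random_sequence(rng, 200)),
             ("c2", random_sequence(rng, 100) + core + random_sequence(rng, 100))]
        )
        index = ReferenceIndex(ref, BuiltinParams())
        placement = builtin_map_read(core[100:200], index)
        assert placement.mapq == 0
        # deterministic tie-break: lowest contig index
        assert placement.contig == "c1"

    def test_one_vs_three_mismatches_matches_exhaustive_oracle(self):
        rng = random.Random(13)
        locus_a = random_sequence(rng, 300)
        # locus B = locus A with 2 extra substitutions inside the read span
        b = list(locus_a)
        b[150] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[150]]
        b[170] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[170]]
        ref = ReferenceSequenceSet(
            [("cA", locus_a), ("cB", "".join(b))]
        )
        read = list(locus_a[100:200])
        read[20] = {"A": "G", "G": "A", "C": "T", "T": "C"}[read[20]]  # 1 vs A, 3 vs B
        read = "".join(read)
        index = ReferenceIndex(ref, BuiltinParams())
        placement = builtin_map_read(read, index)
        oracle = exhaustive_best(ref, read)
        assert (placement.contig, placement.pos) == ("cA", 100)
        assert placement.score == 95
        assert oracle[0][:3] == (95, 0, 100)
        second = next(s for s, ci, off, st in oracle if (ci, off) != (0, 100))
        assert second == 85
        assert placement.mapq == min(60, 6 * (95 - 85)) == 60

    def test_read_shorter_than_k_unmapped(self, unique_index):
        assert builtin_map_read("ACGTACGTAC", unique_index) is None

    def test_random_reads_agree_with_oracle_placement(self, unique_ref, unique_index):
        rng = random.Random(99)
        seq = unique_ref.sequence("chr1")
        for _ in range(25):
            start = rng.randrange(0, 4900)
            read = list(seq[start : start + 100])
            for _ in range(rng.randrange(0, 3)):
                p = rng.randrange(100)
                read[p] = rng.choice([b for b in "ACGT" if b != read[p]])
            read = "".join(read)
            placement = builtin_map_read(read, unique_index)
            oracle = exhaustive_best(unique_ref, read)
            assert (placement.pos, placement.strand) == (oracle[0][2], oracle[0][3])
            assert placement.score == oracle[0][0]


class TestPairRescue:
    def _params(self):
        return BuiltinParams(insert_min=150, insert_max=600)

    def _ref_with_two_copies(self):
        rng = random.Random(21)
        core = random_sequence(rng, 400)
        unique = random_sequence(rng, 400)
        # c1 carries unique+core, c2 carries only the core copy
        return ReferenceSequenceSet(
            [("c1", unique + core), ("c2", core + random_sequence(rng, 50))]
        )

    def test_unique_compatible_mates_proper(self, unique_ref, unique_index):
        seq = unique_ref.sequence("chr1")
        m1 = seq[1000:1100]
        m2 = revcomp(seq[1250:1350])
        params = self._params()
        c1 = unique_index.candidates(m1)
        c2 = unique_index.candidates(m2)
        p1, p2, proper = pair_rescue(c1, c2, 100, 100, unique_index, params)
        assert proper
        assert (p1.pos, p2.pos) == (1000, 1250)
        assert p1.mapq == 60 and p2.mapq == 60

    def test_tied_mate_moved_to_compatible_locus(self):
        ref = self._ref_with_two_copies()
        index = ReferenceIndex(ref, BuiltinParams())
        params = self._params()
        # mate1 unique on c1 (inside the unique prefix); mate2 from the core,
        # tied between c1 and c2, but only the c1 copy is pair-compatible
        m1 = ref.sequence("c1")[250:350]
        m2 = revcomp(ref.sequence("c1")[500:600])
        c1 = index.candidates(m1)
        c2 = index.candidates(m2)
        assert len({(c.contig_idx, c.pos) for c in c2}) == 2  # genuine tie
        p1, p2, proper = pair_rescue(c1, c2, 100, 100, index, params)
        assert proper
        assert p2.contig == "c1" and p2.pos == 500
        # tie excluded by pairing: mapq recomputed, not 0
        assert p2.mapq > 0

    def test_no_compatible_combination_improper(self, unique_ref, unique_index):
        seq = unique_ref.sequence("chr1")
        m1 = seq[100:200]
        m2 = revcomp(seq[3000:3100])  # insert far outside the window
        p1, p2, proper = pair_rescue(
            unique_index.candidates(m1), unique_index.candidates(m2),
            100, 100, unique_index, self._params(),
        )
        assert not proper
        assert (p1.pos, p2.pos) == (100, 3000)


class TestAlignPairs:
    def test_zero_pairs_valid_empty_file_with_header(self, unique_ref, tmp_path):
        out = tmp_path / "empty.bam"
        align_pairs([], unique_ref, BuiltinParams(), out,
                    read_groups=[{"ID": "rg1", "SM": "s1"}])
        with pysam.AlignmentFile(out) as aln:
            assert aln.references == ("chr1",)
            assert aln.header.to_dict()["RG"] == [{"ID": "rg1", "SM": "s1"}]
            assert aln.count(until_eof=True) == 0

    def test_error_free_pairs_full_match_and_conserved_names(
        self, unique_ref, tmp_path
    ):
        rng = random.Random(3)
        seq = unique_ref.sequence("chr1")
        pairs = []
        for i in range(50):
            start = rng.randrange(0, 4600)
            frag = rng.randrange(250, 400)
            pairs.append(
                ReadPair(
                    f"p{i}",
                    (seq[start : start + 100], "I" * 100),
                    (revcomp(seq[start + frag - 100 : start + frag]), "I" * 100),
                )
            )
        out = tmp_path / "aligned.bam"
        align_pairs(pairs, unique_ref, BuiltinParams(insert_min=150, insert_max=600), out)
        with pysam.AlignmentFile(out) as aln:
            records = list(aln.fetch(until_eof=True))
        assert len(records) == 100
        names = {}
        for rec in records:
            assert rec.cigarstring == "100M"
            assert rec.is_proper_pair
            names.setdefault(rec.query_name, []).append(rec.flag & 0xC0)
        assert all(sorted(v) == [0x40, 0x80] for v in names.values())

    def test_repeated_run_byte_identical(self, unique_ref, tmp_path):
        rng = random.Random(5)
        seq = unique_ref.sequence("chr1")
        pairs = [
            ReadPair("a", (seq[10:110], "I" * 100), (revcomp(seq[300:400]), "I" * 100)),
            ReadPair("b", (seq[900:1000], "I" * 100), (revcomp(seq[1200:1300]), "I" * 100)),
        ]
        outs = []
        for run in (1, 2):
            out = tmp_path / f"run{run}.bam"
            align_pairs(pairs, unique_ref, BuiltinParams(random_ties=True, seed=9), out)
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]


class TestExternalBackend:
    def test_template_placeholders_validated(self):
        with pytest.raises(ValueError):
            ExternalBackend("bwa mem {ref} {fq1}")

    def test_failing_command_raises_backend_error(self, unique_ref, tmp_path):
        pairs = [ReadPair("p", ("A" * 100, "I" * 100), ("C" * 100, "I" * 100))]
        with pytest.raises(BackendError):
            align_pairs(
                pairs, unique_ref, ExternalBackend("false {ref} {fq1} {fq2}"),
                tmp_path / "x.bam",
            )

    def test_bwa_cross_check_on_error_free_reads(self, unique_ref, tmp_path):
        """bwa mem as an independent mapper: placements of error-free unique
        reads agree with the builtin mapper and the sampling truth."""
        wrapper = tmp_path / "bwa_wrap.sh"
        wrapper.write_text(
            "#!/bin/sh\nbwa index \"$1\" 2>/dev/null && bwa mem \"$1\" \"$2\" \"$3\" 2>/dev/null\n"
        )
        wrapper.chmod(0o755)
        rng = random.Random(17)
        seq = unique_ref.sequence("chr1")
        pairs, truth = [], {}
        for i in range(40):
            start = rng.randrange(0, 4600)
            frag = 350
            name = f"p{i}"
            truth[name] = start
            pairs.append(
                ReadPair(
                    name,
                    (seq[start : start + 100], "I" * 100),
                    (revcomp(seq[start + frag - 100 : start + frag]), "I" * 100),
                )
            )
        out = tmp_path / "bwa.bam"
        align_pairs(pairs, unique_ref, ExternalBackend(f"{wrapper} {{ref}} {{fq1}} {{fq2}}"), out)
        with pysam.AlignmentFile(out) as aln:
            agree = sum(
                1
                for rec in aln.fetch(until_eof=True)
                if rec.is_read1 and rec.reference_start == truth[rec.query_name]
            )
        assert agree == len(pairs)


class TestSpliceBack:
    CONTIGS = {"chrA": 10_000}

    def _pair(self, name, pos1, pos2, flag_extra=0):
        return [
            dict(name=name, flag=99 | flag_extra, contig="chrA", pos=pos1,
                 cigar="100M", next_contig="chrA", next_pos=pos2),
            dict(name=name, flag=147 | flag_extra, contig="chrA", pos=pos2,
                 cigar="100M", next_contig="chrA", next_pos=pos1),
        ]

    def test_empty_extracted_set_identity(self, tmp_path):
        orig = make_bam(tmp_path / "orig.bam", self.CONTIGS,
                        self._pair("a", 100, 300) + self._pair("b", 500, 700))
        corr = make_bam(tmp_path / "corr.bam", self.CONTIGS, [])
        out = tmp_path / "out.bam"
        counters = splice_back(orig, corr, set(), out)
        assert counters == {"kept": 4, "removed": 0, "added": 0}
        with pysam.AlignmentFile(out) as a, pysam.AlignmentFile(orig) as b:
            got = [r.to_string() for r in a.fetch(until_eof=True)]
            want = [r.to_string() for r in b.fetch(until_eof=True)]
        assert got == want

    def test_name_accounting_including_far_supplementary(self, tmp_path):
        records = (
            self._pair("keepme", 100, 300)
            + self._pair("fixme", 1000, 1200)
            + [dict(name="fixme", flag=99 | 0x800, contig="chrA", pos=9000,
                    cigar="50M", next_contig="chrA", next_pos=1200)]
        )
        orig = make_bam(tmp_path / "orig.bam", self.CONTIGS, records)
        corr = make_bam(tmp_path / "corr.bam", self.CONTIGS,
                        self._pair("fixme", 1050, 1250))
        out = tmp_path / "out.bam"
        counters = splice_back(orig, corr, {"fixme"}, out)
        # supplementary far from the region is removed with its name
        assert counters == {"kept": 2, "removed": 3, "added": 2}
        with pysam.AlignmentFile(out) as aln:
            names = sorted(r.query_name for r in aln.fetch(until_eof=True))
        assert names == ["fixme", "fixme", "keepme", "keepme"]

    def test_contig_length_mismatch_rejected(self, tmp_path):
        orig = make_bam(tmp_path / "orig.bam", {"chrA": 10_000},
                        self._pair("a", 100, 300))
        corr = make_bam(tmp_path / "corr.bam", {"chrA": 9_000}, [])
        with pytest.raises(ValueError, match="length mismatch"):
            splice_back(orig, corr, set(), tmp_path / "out.bam")
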