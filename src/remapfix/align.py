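"""Re-align extracted pairs to the patched reference.

Two backends share one contract: an external command template
(``{ref} {fq1} {fq2}`` placeholders, SAM on stdout) for production aligners,
and a builtin test-grade seed-and-extend mapper so the suite runs without
external binaries. The builtin mapper is ungapped (substitutions only) and
deterministic; its MAPQ preserves the one property downstream analysis
relies on — MAPQ 0 for reads with multiple equally good placements.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from . import __version__
from .extract import ReadPair, pairs_to_fastq, revcomp
from .refpatch import ReferenceSequenceSet


class BackendError(RuntimeError):
    """External aligner command failed."""


@dataclass
class BuiltinParams:
    """Parameters of the builtin mapper.

    ``k``/``seed_step`` control seeding (exact k-mers sampled along the
    read); scoring is match +1 / mismatch -4, ungapped. ``random_ties``
    switches deterministic tie-breaking (lowest contig index, then lowest
    coordinate) to seeded-random placement, which reproduces the realistic
    half-depth split of reads over a false duplication. ``pair_aware``
    enables joint proper-pair placement (mate rescue); with it off, mates
    are placed independently, emulating an upstream whole-genome aligner
    whose multi-mapping reads scatter over the copies on their own.
    """

    k: int = 21
    seed_step: int = 5
    match: int = 1
    mismatch: int = -4
    insert_min: int = 50
    insert_max: int = 1000
    repeat_cap: int = 100
    random_ties: bool = False
    pair_aware: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 11:
            raise ValueError("builtin mapper requires k >= 11")

    @property
    def pair_slack(self) -> int:
        # score cost of one substitution: lose the match, pay the penalty
        return self.match - self.mismatch


@dataclass
class ExternalBackend:
    """Command template producing SAM on stdout, e.g. ``bwa mem {ref} {fq1} {fq2}``."""

    command_template: str

    def __post_init__(self) -> None:
        for ph in ("{ref}", "{fq1}", "{fq2}"):
            if ph not in self.command_template:
                raise ValueError(f"command template missing placeholder {ph}")


@dataclass(frozen=True)
class Candidate:
    contig_idx: int
    pos: int
    strand: int  # 0 forward, 1 reverse
    score: int
    mismatches: int


@dataclass
class Placement:
    contig: str
    pos: int
    strand: int
    score: int
    mapq: int
    mismatches: int
    mapped: bool = True


class ReferenceIndex:
    """Exact k-mer index over a reference, for seed lookup."""

    def __init__(self, ref: ReferenceSequenceSet, params: BuiltinParams | None = None):
        self.params = params or BuiltinParams()
        self.names = ref.names
        self.arrays = [
            np.frombuffer(seq.encode("ascii"), dtype=np.uint8) for _, seq in ref.contigs
        ]
        k = self.params.k
        index: dict[bytes, list[tuple[int, int]]] = {}
        for ci, (_, seq) in enumerate(ref.contigs):
            enc = seq.encode("ascii")
            for pos in range(len(enc) - k + 1):
                kmer = enc[pos : pos + k]
                if b"N" in kmer:
                    continue
                index.setdefault(kmer, []).append((ci, pos))
        cap = self.params.repeat_cap
        self.index = {km: hits for km, hits in index.items() if len(hits) <= cap}

    def candidates(self, seq: str) -> list[Candidate]:
        """All diagonal-clustered seed candidates, fully scored, best first."""
        p = self.params
        k = p.k
        out: list[Candidate] = []
        for strand, s in ((0, seq), (1, revcomp(seq))):
            length = len(s)
            if length < k:
                continue
            enc = s.encode("ascii")
            read_arr = np.frombuffer(enc, dtype=np.uint8)
            offsets = list(range(0, length - k + 1, p.seed_step))
            if offsets[-1] != length - k:
                offsets.append(length - k)
            diagonals: set[tuple[int, int]] = set()
            for off in offsets:
                for ci, pos in self.index.get(enc[off : off + k], ()):
                    diagonals.add((ci, pos - off))
            for ci, diag in diagonals:
                arr = self.arrays[ci]
                if diag < 0 or diag + length > arr.size:
                    continue
                mm = int(np.count_nonzero(arr[diag : diag + length] != read_arr))
                score = (length - mm) * p.match + mm * p.mismatch
                if score <= 0:
                    continue
                out.append(Candidate(ci, diag, strand, score, mm))
        out.sort(key=lambda c: (-c.score, c.contig_idx, c.pos, c.strand))
        return out


def _mapq_from_scores(best: int, second: int | None) -> int:
    if second is None:
        return min(60, 6 * best)
    if second >= best:
        return 0
    return min(60, 6 * (best - second))


def builtin_map_read(
    seq: str, index: ReferenceIndex, params: BuiltinParams | None = None
) -> Placement | None:
    """Map one read: best locus, full-match CIGAR span, score, MAPQ.

    Returns None (unmapped) when the read is shorter than k or no seed
    yields a positive-score candidate. Ties give MAPQ 0 and are broken
    deterministically (lowest contig index, then coordinate).
    """
    params = params or index.params
    cands = index.candidates(seq)
    if not cands:
        return None
    best = cands[0]
    second = cands[1].score if len(cands) > 1 else None
    return Placement(
        contig=index.names[best.contig_idx],
        pos=best.pos,
        strand=best.strand,
        score=best.score,
        mapq=_mapq_from_scores(best.score, second),
        mismatches=best.mismatches,
    )


def _compatible(
    c1: Candidate, c2: Candidate, len1: int, len2: int, params: BuiltinParams
) -> bool:
    """Proper-pair test: same contig, opposite strands, insert in window."""
    if c1.contig_idx != c2.contig_idx or c1.strand == c2.strand:
        return False
    if c1.strand == 0:
        left, right_end = c1.pos, c2.pos + len2
    else:
        left, right_end = c2.pos, c1.pos + len1
    tlen = right_end - left
    return params.insert_min <= tlen <= params.insert_max and tlen >= max(len1, len2)


def _independent(
    cands: list[Candidate], index: ReferenceIndex, rng: np.random.Generator | None
) -> Placement:
    best = cands[0]
    ties = [c for c in cands if c.score == best.score]
    if len(ties) > 1 and rng is not None:
        best = ties[int(rng.integers(len(ties)))]
    second = None
    for c in cands:
        if (c.contig_idx, c.pos, c.strand) != (best.contig_idx, best.pos, best.strand):
            second = c.score
            break
    return Placement(
        index.names[best.contig_idx],
        best.pos,
        best.strand,
        best.score,
        _mapq_from_scores(best.score, second),
        best.mismatches,
    )


def pair_rescue(
    cands1: list[Candidate],
    cands2: list[Candidate],
    len1: int,
    len2: int,
    index: ReferenceIndex,
    params: BuiltinParams,
    rng: np.random.Generator | None = None,
) -> tuple[Placement | None, Placement | None, bool]:
    """Joint placement of a pair over the mates' candidate lists.

    Prefers the compatible combination (same contig, opposite strands,
    insert inside the window) with the highest summed score, considering
    for each mate only candidates within one substitution of its own best —
    that is how a tied or slightly suboptimal mate gets moved next to its
    partner. When several compatible combinations tie, both mates get
    MAPQ 0 and the tie is broken deterministically or (seeded) randomly.
    """
    if not cands1 and not cands2:
        return None, None, False
    if not cands1:
        return None, _independent(cands2, index, rng), False
    if not cands2:
        return _independent(cands1, index, rng), None, False

    slack = params.pair_slack
    top1, top2 = cands1[0].score, cands2[0].score
    near1 = [c for c in cands1 if c.score >= top1 - slack]
    near2 = [c for c in cands2 if c.score >= top2 - slack]
    combos = [
        (c1, c2)
        for c1 in near1
        for c2 in near2
        if _compatible(c1, c2, len1, len2, params)
    ]
    if not combos:
        return (
            _independent(cands1, index, rng),
            _independent(cands2, index, rng),
            False,
        )

    best_sum = max(c1.score + c2.score for c1, c2 in combos)
    best_combos = sorted(
        (pair for pair in combos if pair[0].score + pair[1].score == best_sum),
        key=lambda p: (p[0].contig_idx, p[0].pos, p[0].strand, p[1].pos),
    )
    if len(best_combos) > 1 and rng is not None:
        chosen = best_combos[int(rng.integers(len(best_combos)))]
    else:
        chosen = best_combos[0]

    placements = []
    for mate_idx, cand in enumerate(chosen):
        key = (cand.contig_idx, cand.pos, cand.strand)
        spots = {(p[mate_idx].contig_idx, p[mate_idx].pos, p[mate_idx].strand)
                 for p in best_combos}
        if len(spots) > 1:
            mapq = 0
        else:
            alt = None
            for c1, c2 in combos:
                other = (c1, c2)[mate_idx]
                if (other.contig_idx, other.pos, other.strand) != key:
                    s = c1.score + c2.score
                    alt = s if alt is None else max(alt, s)
            if alt is None:
                mapq = _mapq_from_scores(cand.score, None)
            else:
                mapq = _mapq_from_scores(best_sum, alt)
        placements.append(
            Placement(index.names[cand.contig_idx], cand.pos, cand.strand,
                      cand.score, mapq, cand.mismatches)
        )
    return placements[0], placements[1], True


def _build_header(
    ref: ReferenceSequenceSet, read_groups: Sequence[dict] | None
) -> dict:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in ref.contigs],
        "PG": [{"ID": "remapfix", "PN": "remapfix", "VN": __version__}],
    }
    if read_groups:
        header["RG"] = list(read_groups)
    return header


def _segment(
    header: pysam.AlignmentHeader,
    pair: ReadPair,
    which: int,
    placement: Placement | None,
    mate: Placement | None,
    proper: bool,
    tlen: int,
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seq, qual = pair.mate1 if which == 1 else pair.mate2
    flag = 0x1 | (0x40 if which == 1 else 0x80)
    if proper:
        flag |= 0x2
    if placement is None:
        flag |= 0x4
    elif placement.strand == 1:
        flag |= 0x10
        seq, qual = revcomp(seq), qual[::-1]
    if mate is None:
        flag |= 0x8
    elif mate.strand == 1:
        flag |= 0x20
    seg.query_name = pair.name
    seg.flag = flag
    seg.query_sequence = seq
    seg.query_qualities = pysam.qualitystring_to_array(qual)
    if placement is not None:
        seg.reference_id = header.get_tid(placement.contig)
        seg.reference_start = placement.pos
        seg.mapping_quality = placement.mapq
        seg.cigarstring = f"{len(seq)}M"
        seg.set_tag("NM", placement.mismatches, "i")
    else:
        anchor = mate  # SAM convention: unmapped read sits at its mate
        seg.reference_id = header.get_tid(anchor.contig) if anchor else -1
        seg.reference_start = anchor.pos if anchor else -1
        seg.mapping_quality = 0
    if mate is not None:
        seg.next_reference_id = header.get_tid(mate.contig)
        seg.next_reference_start = mate.pos
    else:
        seg.next_reference_id = seg.reference_id
        seg.next_reference_start = seg.reference_start
    seg.template_length = tlen
    if pair.read_group:
        seg.set_tag("RG", pair.read_group, "Z")
    return seg


def _sort_index(unsorted_path: str, out_path: str) -> None:
    pysam.sort("--no-PG", "-o", str(out_path), str(unsorted_path))
    pysam.index(str(out_path))


def align_pairs(
    pairs: list[ReadPair],
    ref: ReferenceSequenceSet,
    backend: BuiltinParams | ExternalBackend,
    out_bam: str | Path,
    read_groups: Sequence[dict] | None = None,
) -> None:
    """Map pairs to ``ref`` and write a coordinate-sorted, indexed BAM.

    Every input pair appears in the output, mapped or unmapped. The header
    lists all reference contigs (including decoys) plus the supplied
    read-group definitions.
    """
    if isinstance(backend, ExternalBackend):
        _align_external(pairs, ref, backend, out_bam)
        return
    index = ReferenceIndex(ref, backend)
    rng = np.random.default_rng(backend.seed) if backend.random_ties else None
    header_dict = _build_header(ref, read_groups)
    with tempfile.TemporaryDirectory() as tmp:
        unsorted = str(Path(tmp) / "unsorted.bam")
        with pysam.AlignmentFile(unsorted, "wb", header=header_dict) as out:
            header = out.header
            for pair in pairs:
                c1 = index.candidates(pair.mate1[0])
                c2 = index.candidates(pair.mate2[0])
                if backend.pair_aware:
                    p1, p2, proper = pair_rescue(
                        c1, c2, len(pair.mate1[0]), len(pair.mate2[0]),
                        index, backend, rng,
                    )
                else:
                    p1 = _independent(c1, index, rng) if c1 else None
                    p2 = _independent(c2, index, rng) if c2 else None
                    proper = bool(
                        p1 and p2
                        and p1.contig == p2.contig
                        and p1.strand != p2.strand
                    )
                tlen = 0
                if proper and p1 and p2:
                    left = min(p1.pos, p2.pos)
                    right = max(p1.pos + len(pair.mate1[0]), p2.pos + len(pair.mate2[0]))
                    tlen = right - left
                t1 = tlen if (p1 and p1.strand == 0) else -tlen
                out.write(_segment(header, pair, 1, p1, p2, proper, t1))
                out.write(_segment(header, pair, 2, p2, p1, proper, -t1))
        _sort_index(unsorted, str(out_bam))


def _align_external(
    pairs: list[ReadPair],
    ref: ReferenceSequenceSet,
    backend: ExternalBackend,
    out_bam: str | Path,
) -> None:
    with tempfile.TemporaryDirectory() as tmp:
        tmpdir = Path(tmp)
        ref_path = tmpdir / "ref.fa"
        ref.to_fasta(ref_path)
        fq1, fq2 = tmpdir / "r1.fq", tmpdir / "r2.fq"
        pairs_to_fastq(pairs, fq1, fq2)
        argv = [
            tok.format(ref=str(ref_path), fq1=str(fq1), fq2=str(fq2))
            for tok in shlex.split(backend.command_template)
        ]
        proc = subprocess.run(argv, capture_output=True)
        if proc.returncode != 0:
            raise BackendError(
                f"aligner command failed ({proc.returncode}): "
                f"{proc.stderr.decode(errors='replace')[-2000:]}"
            )
        sam_path = tmpdir / "out.sam"
        sam_path.write_bytes(proc.stdout)
        unsorted = tmpdir / "unsorted.bam"
        with pysam.AlignmentFile(str(sam_path)) as sam:
            lengths = ref.lengths
            for name, ln in zip(sam.references, sam.lengths):
                if lengths.get(name) != ln:
                    raise BackendError(
                        f"backend header contig {name} ({ln} bp) does not match "
                        f"the patched reference"
                    )
            with pysam.AlignmentFile(str(unsorted), "wb", template=sam) as out:
                for rec in sam:
                    out.write(rec)
        _sort_index(str(unsorted), str(out_bam))


def splice_back(
    original_bam: str | Path,
    corrected_bam: str | Path,
    extracted_names: set[str],
    out_bam: str | Path,
) -> dict[str, int]:
    """Genome-wide corrected file: original minus extracted names, plus
    corrected records, under the patched-reference header.

    Removal is by read name across the whole file (primary, secondary and
    supplementary records alike), so no orphaned records survive.
    """
    counters = {"kept": 0, "removed": 0, "added": 0}
    with tempfile.TemporaryDirectory() as tmp:
        unsorted = str(Path(tmp) / "unsorted.bam")
        with pysam.AlignmentFile(str(corrected_bam)) as corr, pysam.AlignmentFile(
            str(original_bam)
        ) as orig:
            orig_lengths = dict(zip(orig.references, orig.lengths))
            corr_lengths = dict(zip(corr.references, corr.lengths))
            for name, ln in orig_lengths.items():
                if name in corr_lengths and corr_lengths[name] != ln:
                    raise ValueError(
                        f"contig {name} length mismatch between original "
                        f"({ln}) and corrected ({corr_lengths[name]}) files"
                    )
            header = corr.header.to_dict()
            have_rg = {rg["ID"] for rg in header.get("RG", [])}
            for rg in orig.header.to_dict().get("RG", []):
                if rg["ID"] not in have_rg:
                    header.setdefault("RG", []).append(rg)
            with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
                out_header = out.header
                for rec in orig.fetch(until_eof=True):
                    if rec.query_name in extracted_names:
                        counters["removed"] += 1
                        continue
                    out.write(
                        pysam.AlignedSegment.fromstring(rec.to_string(), out_header)
                    )
                    counters["kept"] += 1
                for rec in corr.fetch(until_eof=True):
                    out.write(
                        pysam.AlignedSegment.fromstring(rec.to_string(), out_header)
                    )
                    counters["added"] += 1
        _sort_index(unsorted, str(out_bam))
    return counters
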