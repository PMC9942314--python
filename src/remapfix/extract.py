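"""Pull affected read pairs out of a coordinate-sorted alignment file.

The selection mirrors ``samtools view -F 2316``: drop unmapped, mate-unmapped,
secondary, and supplementary records; duplicate-flagged and QC-fail records
are deliberately retained. Pairs are reconstituted with unique names; a
singleton whose mate lies outside the fetched intervals gets one rescue
attempt at the recorded mate position before the pair is dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .intervals import ErrorRegionSet, GenomicInterval

logger = logging.getLogger(__name__)

#: flag bits excluded everywhere reads are selected or piled up
#: (unmapped | mate-unmapped | secondary | supplementary) == 2316
EXCLUDE_FLAGS = 0x4 | 0x8 | 0x100 | 0x800

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ReadPair:
    """One paired-end read in original (sequencer) orientation."""

    name: str
    mate1: tuple[str, str]  # (sequence, Phred+33 qualities)
    mate2: tuple[str, str]
    read_group: str | None = None

    def __post_init__(self) -> None:
        for seq, qual in (self.mate1, self.mate2):
            if len(seq) != len(qual):
                raise ValueError(
                    f"read {self.name}: sequence/quality length mismatch"
                )


@dataclass
class ExtractionStats:
    selected_records: int = 0
    pairs_emitted: int = 0
    pairs_rescued: int = 0
    dropped_singletons: int = 0
    dropped_ambiguous: int = 0
    skipped_contigs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1) + "\n")


def _require_index(aln: pysam.AlignmentFile) -> None:
    if not aln.has_index():
        raise FileNotFoundError(
            f"{aln.filename.decode()} is not indexed; run 'samtools index' first"
        )


def select_alignments(
    aln_path: str | Path,
    regions: ErrorRegionSet | list[GenomicInterval],
    stats: ExtractionStats | None = None,
) -> list[pysam.AlignedSegment]:
    """Primary, both-mates-mapped records overlapping any homolog interval.

    Each record is reported once even when intervals overlap. Region contigs
    absent from the header are skipped with a warning.
    """
    intervals = (
        regions.all_homolog_intervals()
        if isinstance(regions, ErrorRegionSet)
        else regions
    )
    records: list[pysam.AlignedSegment] = []
    seen: set[tuple] = set()
    with pysam.AlignmentFile(str(aln_path)) as aln:
        _require_index(aln)
        header_contigs = set(aln.references)
        for iv in intervals:
            if iv.contig not in header_contigs:
                logger.warning("region contig %s absent from header; skipped", iv.contig)
                if stats is not None and iv.contig not in stats.skipped_contigs:
                    stats.skipped_contigs.append(iv.contig)
                continue
            for rec in aln.fetch(iv.contig, iv.start, iv.end):
                if rec.flag & EXCLUDE_FLAGS:
                    continue
                key = (rec.query_name, rec.flag, rec.reference_id, rec.reference_start)
                if key in seen:
                    continue
                seen.add(key)
                records.append(rec)
    if stats is not None:
        stats.selected_records = len(records)
    return records


def _oriented(rec: pysam.AlignedSegment) -> tuple[str, str]:
    """Sequence/qualities restored to original read orientation."""
    seq = rec.query_sequence
    qual = pysam.qualities_to_qualitystring(rec.query_qualities)
    if rec.is_reverse:
        return revcomp(seq), qual[::-1]
    return seq, qual


def _read_group(rec: pysam.AlignedSegment) -> str | None:
    try:
        return rec.get_tag("RG")
    except KeyError:
        return None


def _rescue_mate(
    aln: pysam.AlignmentFile, rec: pysam.AlignedSegment, window: int
) -> pysam.AlignedSegment | None:
    """Fetch the missing mate at its recorded position, same flag mask.

    Only mates on the same contig within ``window`` of the selected read
    are rescued; farther (discordant) mates leave the singleton dropped.
    """
    if rec.next_reference_id < 0:
        return None
    if rec.next_reference_id != rec.reference_id:
        return None
    contig = rec.next_reference_name
    pos = rec.next_reference_start
    if abs(pos - rec.reference_start) > window:
        return None
    want_first = rec.is_read2  # the missing mate is the other one
    for cand in aln.fetch(contig, max(0, pos - window), pos + window + 1):
        if cand.flag & EXCLUDE_FLAGS:
            continue
        if cand.query_name != rec.query_name:
            continue
        if cand.is_read1 == want_first and cand.reference_start == pos:
            return cand
    return None


def pair_and_dedup(
    records: list[pysam.AlignedSegment],
    aln_path: str | Path,
    rescue_window: int = 1000,
    stats: ExtractionStats | None = None,
) -> list[ReadPair]:
    """Group records into complete, uniquely named pairs.

    Names with more than two surviving records, or with two copies of the
    same mate, are dropped entirely; singletons are rescued from the file
    when the mate sits within ``rescue_window`` of its recorded position,
    otherwise dropped.
    """
    stats = stats if stats is not None else ExtractionStats()
    by_name: dict[str, list[pysam.AlignedSegment]] = {}
    for rec in records:
        by_name.setdefault(rec.query_name, []).append(rec)

    pairs: list[ReadPair] = []
    with pysam.AlignmentFile(str(aln_path)) as aln:
        _require_index(aln)
        for name, recs in by_name.items():
            if len(recs) > 2:
                stats.dropped_ambiguous += 1
                continue
            if len(recs) == 2:
                r1 = next((r for r in recs if r.is_read1), None)
                r2 = next((r for r in recs if r.is_read2), None)
                if r1 is None or r2 is None:  # two copies of the same mate
                    stats.dropped_ambiguous += 1
                    continue
            else:
                (only,) = recs
                mate = _rescue_mate(aln, only, rescue_window)
                if mate is None:
                    stats.dropped_singletons += 1
                    continue
                stats.pairs_rescued += 1
                r1, r2 = (only, mate) if only.is_read1 else (mate, only)
            pairs.append(
                ReadPair(
                    name=name,
                    mate1=_oriented(r1),
                    mate2=_oriented(r2),
                    read_group=_read_group(r1) or _read_group(r2),
                )
            )
    stats.pairs_emitted = len(pairs)
    return pairs


def pairs_to_fastq(
    pairs: list[ReadPair], fq1_path: str | Path, fq2_path: str | Path
) -> None:
    """Write mate1/mate2 FASTQ streams (Phred+33, no /1 /2 name suffixes)."""
    with open(fq1_path, "w") as f1, open(fq2_path, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.name}\n{pair.mate1[0]}\n+\n{pair.mate1[1]}\n")
            f2.write(f"@{pair.name}\n{pair.mate2[0]}\n+\n{pair.mate2[1]}\n")


def fastq_to_pairs(fq1_path: str | Path, fq2_path: str | Path) -> list[ReadPair]:
    """Read two synchronized FASTQ streams back into ReadPairs."""
    with pysam.FastxFile(str(fq1_path)) as f1, pysam.FastxFile(str(fq2_path)) as f2:
        pairs = []
        for e1, e2 in zip(f1, f2):
            if e1.name != e2.name:
                raise ValueError(f"FASTQ name mismatch: {e1.name} vs {e2.name}")
            pairs.append(
                ReadPair(e1.name, (e1.sequence, e1.quality), (e2.sequence, e2.quality))
            )
    return pairs
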