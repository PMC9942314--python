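"""Desk-scale pileup SNV genotyper and truth-VCF comparator.

The genotyper is a deliberately simple stand-in for a production caller:
per-position base counts from reads passing the extraction flag mask plus
MAPQ/base-quality thresholds, with an allele-fraction band separating
heterozygous from homozygous-alternate calls. The comparator matches truth
records exactly on (contig, position, ref, alt, genotype) — stricter than
haplotype-aware benchmarking tools, which is acceptable for SNVs on a
simulated truth set.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .extract import EXCLUDE_FLAGS
from .intervals import GenomicInterval, normalize_intervals
from .refpatch import ReferenceSequenceSet

GENOTYPES = ("hom-ref", "het", "hom-alt")


@dataclass(frozen=True)
class VariantCall:
    """A biallelic SNV call (0-based position internally)."""

    contig: str
    pos: int
    ref: str
    alt: str
    genotype: str
    depth: int = 0
    alt_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide alleles are supported")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction outside [0, 1]")

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt, self.genotype)


@dataclass
class BenchmarkSummary:
    tp: int
    fp: int
    fn: int
    skipped_multiallelic: int = 0

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None

    @property
    def f_measure(self) -> float | None:
        return f_measure(self.precision, self.recall)


def f_measure(precision: float | None, recall: float | None) -> float | None:
    """Harmonic mean of precision and recall (None when undefined)."""
    if precision is None or recall is None or precision + recall == 0:
        return None
    return 2.0 * precision * recall / (precision + recall)


def pileup_genotype(
    aln_path: str | Path,
    ref: ReferenceSequenceSet,
    regions: Sequence[GenomicInterval],
    min_mapq: int = 20,
    min_baseq: int = 13,
    min_depth: int = 4,
    het_band: tuple[float, float] = (0.2, 0.8),
) -> list[VariantCall]:
    """Call SNVs by per-position base counting inside ``regions``.

    At each position the most frequent non-reference base with fraction f of
    the passing depth yields a het call when f lies in ``het_band`` and a
    hom-alt call when f exceeds the band; hard-masked ('N') reference
    positions are skipped.
    """
    calls: list[VariantCall] = []
    lengths = ref.lengths
    with pysam.AlignmentFile(str(aln_path)) as aln:
        for iv in normalize_intervals(regions):
            if iv.contig not in aln.references or iv.contig not in lengths:
                continue
            seq = ref.sequence(iv.contig)
            for col in aln.pileup(
                iv.contig,
                iv.start,
                min(iv.end, lengths[iv.contig]),
                truncate=True,
                stepper="all",
                flag_filter=EXCLUDE_FLAGS,
                min_base_quality=0,
                max_depth=100000,
            ):
                pos = col.reference_pos
                ref_base = seq[pos]
                if ref_base == "N":
                    continue
                counts: Counter[str] = Counter()
                for p in col.pileups:
                    if p.is_del or p.is_refskip or p.query_position is None:
                        continue
                    rec = p.alignment
                    if rec.mapping_quality < min_mapq:
                        continue
                    quals = rec.query_qualities
                    if quals is not None and quals[p.query_position] < min_baseq:
                        continue
                    counts[rec.query_sequence[p.query_position]] += 1
                depth = sum(counts.values())
                if depth < min_depth:
                    continue
                alt_counts = [
                    (n, b) for b, n in counts.items() if b != ref_base and b != "N"
                ]
                if not alt_counts:
                    continue
                n_alt, alt = max(alt_counts)
                frac = n_alt / depth
                if frac < het_band[0]:
                    continue
                genotype = "het" if frac <= het_band[1] else "hom-alt"
                calls.append(
                    VariantCall(iv.contig, pos, ref_base, alt, genotype, depth, frac)
                )
    return calls


# ---------------------------------------------------------------------------
# VCF I/O (VCF 4.2, GT:DP) — 1-based positions at this boundary only


def _vcf_header(
    contigs: Mapping[str, int], samples: Sequence[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for s in samples:
        header.add_sample(s)
    return header


_GT_CODE = {"hom-ref": (0, 0), "het": (0, 1), "hom-alt": (1, 1)}


def write_vcf(
    calls: Sequence[VariantCall],
    contigs: Mapping[str, int],
    path: str | Path,
    sample: str = "sample1",
) -> None:
    header = _vcf_header(contigs, [sample])
    order = {name: i for i, name in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for call in sorted(calls, key=lambda c: (order[c.contig], c.pos)):
            rec = vcf.new_record(
                contig=call.contig,
                start=call.pos,
                stop=call.pos + 1,
                alleles=(call.ref, call.alt),
                filter="PASS",
            )
            rec.samples[sample]["GT"] = _GT_CODE[call.genotype]
            rec.samples[sample]["DP"] = call.depth
            rec.samples[sample].phased = False
            vcf.write(rec)


def write_cohort_vcf(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
    contigs: Mapping[str, int],
    path: str | Path,
) -> None:
    """Merge per-sample call lists into one multi-sample VCF.

    At the union of called sites, samples without a call are written as
    hom-ref with missing DP.
    """
    samples = list(calls_by_sample)
    sites: dict[tuple[str, int, str, str], dict[str, VariantCall]] = {}
    for sample, calls in calls_by_sample.items():
        for call in calls:
            site = sites.setdefault((call.contig, call.pos, call.ref, call.alt), {})
            site[sample] = call
    header = _vcf_header(contigs, samples)
    order = {name: i for i, name in enumerate(contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for (contig, pos, ref, alt), per_sample in sorted(
            sites.items(), key=lambda kv: (order[kv[0][0]], kv[0][1], kv[0][3])
        ):
            rec = vcf.new_record(
                contig=contig, start=pos, stop=pos + 1, alleles=(ref, alt),
                filter="PASS",
            )
            for sample in samples:
                call = per_sample.get(sample)
                rec.samples[sample]["GT"] = (
                    _GT_CODE[call.genotype] if call else (0, 0)
                )
                if call:
                    rec.samples[sample]["DP"] = call.depth
                rec.samples[sample].phased = False
            vcf.write(rec)


def read_vcf_calls(
    path: str | Path, sample: str | None = None
) -> tuple[list[VariantCall], int]:
    """Read biallelic SNVs from a VCF; returns (calls, n_skipped_multiallelic).

    Multiallelic or non-SNV records are skipped with a counter; hom-ref and
    uncalled genotypes yield no call.
    """
    calls: list[VariantCall] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if sample is None:
            sample = sample_names[0] if sample_names else None
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1:
                skipped += 1
                continue
            fmt = rec.samples[sample] if sample else None
            gt = fmt.get("GT") if fmt else (0, 1)
            if gt is None or any(a is None for a in gt):
                continue
            n_alt = sum(1 for a in gt if a != 0)
            if n_alt == 0:
                continue
            genotype = "het" if n_alt == 1 else "hom-alt"
            dp = (fmt.get("DP") if fmt else None) or 0
            calls.append(
                VariantCall(rec.contig, rec.pos - 1, ref, alt, genotype, dp)
            )
    return calls, skipped


def _in_regions(call: VariantCall, regions: Sequence[GenomicInterval] | None) -> bool:
    if regions is None:
        return True
    return any(
        iv.contig == call.contig and iv.start <= call.pos < iv.end for iv in regions
    )


def compare_to_truth(
    calls: Iterable[VariantCall],
    truth: Iterable[VariantCall],
    confident: Sequence[GenomicInterval] | None = None,
    skipped_multiallelic: int = 0,
) -> BenchmarkSummary:
    """Exact-genotype benchmark of calls against a truth set.

    Both sets are restricted to the confident regions first. A truth record
    is a TP when a call matches contig, position, ref, alt, and genotype;
    a genotype mismatch at the same site counts as FP + FN (conservative).
    """
    call_keys = {c.key for c in calls if _in_regions(c, confident)}
    truth_keys = {t.key for t in truth if _in_regions(t, confident)}
    tp = len(call_keys & truth_keys)
    return BenchmarkSummary(
        tp=tp,
        fp=len(call_keys - truth_keys),
        fn=len(truth_keys - call_keys),
        skipped_multiallelic=skipped_multiallelic,
    )
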