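"""Per-region statistics that detect reference errors and confirm fixes.

A false duplication splits reads over two copies: depth drops toward half
and multi-mapping reads pile up at MAPQ 0. A collapsed duplication attracts
the missing paralog's reads: depth rises toward double and paralogous
sequence variants masquerade as heterozygotes in every sample, driving the
site inbreeding coefficient F = 1 - H_obs/H_exp strongly negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .extract import EXCLUDE_FLAGS
from .intervals import GenomicInterval, normalize_intervals


@dataclass
class MapqSummary:
    label: str
    n_records: int
    mean_mapq: float | None
    n_mapq0: int
    frac_mapq0: float | None


@dataclass
class DepthSummary:
    label: str
    mean_depth: float
    baseline_mean_depth: float
    depth_ratio: float | None


@dataclass
class RegionDiagnostics:
    """Bundle of the per-region metrics used before/after a fix."""

    label: str
    mapq: MapqSummary
    depth: DepthSummary
    site_f: dict[int, float | None] = field(default_factory=dict)

    @property
    def median_f(self) -> float | None:
        vals = [v for v in self.site_f.values() if v is not None]
        return float(np.median(vals)) if vals else None


def _passes(rec: pysam.AlignedSegment) -> bool:
    return not rec.flag & EXCLUDE_FLAGS


def mapq_summary(
    aln_path: str | Path, regions: Mapping[str, Sequence[GenomicInterval]]
) -> dict[str, MapqSummary]:
    """MAPQ statistics per labelled region.

    Records pass the same exclusion mask as extraction; a record overlapping
    several labelled regions contributes to each of them, but only once per
    region even when the region has several intervals.
    """
    out: dict[str, MapqSummary] = {}
    with pysam.AlignmentFile(str(aln_path)) as aln:
        for label, intervals in regions.items():
            mapqs: list[int] = []
            seen: set[tuple] = set()
            for iv in normalize_intervals(intervals):
                if iv.contig not in aln.references:
                    continue
                for rec in aln.fetch(iv.contig, iv.start, iv.end):
                    if not _passes(rec):
                        continue
                    key = (rec.query_name, rec.flag, rec.reference_start)
                    if key in seen:
                        continue
                    seen.add(key)
                    mapqs.append(rec.mapping_quality)
            n = len(mapqs)
            n0 = sum(1 for q in mapqs if q == 0)
            out[label] = MapqSummary(
                label=label,
                n_records=n,
                mean_mapq=float(np.mean(mapqs)) if n else None,
                n_mapq0=n0,
                frac_mapq0=n0 / n if n else None,
            )
    return out


def _region_depth(
    aln: pysam.AlignmentFile,
    intervals: Sequence[GenomicInterval],
    exclude_duplicates: bool = False,
) -> float:
    """Mean per-position pileup depth over a set of intervals."""
    mask = EXCLUDE_FLAGS | (0x400 if exclude_duplicates else 0)

    def keep(rec: pysam.AlignedSegment) -> bool:
        return not rec.flag & mask

    total = 0
    length = 0
    for iv in normalize_intervals(intervals):
        if iv.contig not in aln.references:
            length += len(iv)
            continue
        cov = aln.count_coverage(
            iv.contig, iv.start, iv.end, quality_threshold=0, read_callback=keep
        )
        total += int(np.sum(cov))
        length += len(iv)
    if length == 0:
        raise ValueError("zero-length interval set for depth computation")
    return total / length


def depth_summary(
    aln_path: str | Path,
    regions: Mapping[str, Sequence[GenomicInterval]],
    baseline: Sequence[GenomicInterval],
    exclude_duplicates: bool = False,
) -> dict[str, DepthSummary]:
    """Mean depth per region and its ratio to a baseline interval set.

    The baseline stands for the unaffected rest of the genome and must be
    disjoint from the error regions; a healthy fixed region has ratio ~1,
    a false duplication ~0.5 pre-fix, a collapsed duplication ~2 pre-fix.
    """
    if not baseline or sum(len(iv) for iv in baseline) == 0:
        raise ValueError("baseline intervals must cover at least one base")
    out: dict[str, DepthSummary] = {}
    with pysam.AlignmentFile(str(aln_path)) as aln:
        base = _region_depth(aln, baseline, exclude_duplicates)
        for label, intervals in regions.items():
            mean = _region_depth(aln, intervals, exclude_duplicates)
            out[label] = DepthSummary(
                label=label,
                mean_depth=mean,
                baseline_mean_depth=base,
                depth_ratio=mean / base if base > 0 else None,
            )
    return out


def inbreeding_coefficient(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float | None:
    """Single-site inbreeding coefficient F = 1 - H_obs/H_exp.

    Allele frequency and expected heterozygosity are taken from the called
    genotypes themselves (plain single-population estimator, no
    population-structure adjustment). Returns None when H_exp is zero
    (monomorphic site) or no genotype was called.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        return None
    p = (2 * n_hom_ref + n_het) / (2 * n)
    h_exp = 2.0 * p * (1.0 - p)
    if h_exp == 0.0:
        return None
    h_obs = n_het / n
    return 1.0 - h_obs / h_exp


@dataclass
class SiteStat:
    contig: str
    pos: int  # 0-based
    region_class: str
    mean_depth: float | None
    f: float | None


def _classify(
    contig: str, pos: int, classes: Mapping[str, Sequence[GenomicInterval]]
) -> str:
    for name, intervals in classes.items():
        for iv in intervals:
            if iv.contig == contig and iv.start <= pos < iv.end:
                return name
    return "rest"


def cohort_site_stats(
    vcf_path: str | Path,
    region_classes: Mapping[str, Sequence[GenomicInterval]],
) -> list[SiteStat]:
    """Per-variant mean sample depth and inbreeding coefficient, labelled by
    region class ('rest' for sites outside every class)."""
    out: list[SiteStat] = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            counts = [0, 0, 0]
            depths: list[int] = []
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                n_alt = sum(1 for a in gt if a != 0)
                counts[min(n_alt, 2) if len(gt) == 2 else n_alt] += 1
                dp = sample.get("DP")
                if dp is not None:
                    depths.append(dp)
            out.append(
                SiteStat(
                    contig=rec.contig,
                    pos=rec.pos - 1,
                    region_class=_classify(rec.contig, rec.pos - 1, region_classes),
                    mean_depth=float(np.mean(depths)) if depths else None,
                    f=inbreeding_coefficient(*counts),
                )
            )
    return out


def summarize_class(stats: Iterable[SiteStat], field_name: str) -> dict[str, dict]:
    """Boxplot-style summaries (mean, quartiles, whiskers at 1.5 IQR) of one
    site statistic, grouped by region class."""
    grouped: dict[str, list[float]] = {}
    for s in stats:
        val = getattr(s, field_name)
        if val is not None:
            grouped.setdefault(s.region_class, []).append(val)
    out = {}
    for name, vals in grouped.items():
        arr = np.asarray(vals, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        in_whisker = arr[(arr >= q1 - 1.5 * iqr) & (arr <= q3 + 1.5 * iqr)]
        out[name] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "whisker_low": float(in_whisker.min()),
            "whisker_high": float(in_whisker.max()),
        }
    return out


def write_report(
    rows: Iterable[MapqSummary | DepthSummary], path: str | Path
) -> None:
    """TSV report, one row per region per metric set."""
    rows = list(rows)
    with open(path, "w") as fh:
        for row in rows:
            if isinstance(row, MapqSummary):
                fh.write(
                    f"{row.label}\tmapq\tn_records={row.n_records}\t"
                    f"mean_mapq={row.mean_mapq}\tn_mapq0={row.n_mapq0}\t"
                    f"frac_mapq0={row.frac_mapq0}\n"
                )
            else:
                fh.write(
                    f"{row.label}\tdepth\tmean_depth={row.mean_depth:.4f}\t"
                    f"baseline={row.baseline_mean_depth:.4f}\t"
                    f"depth_ratio={row.depth_ratio}\n"
                )
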