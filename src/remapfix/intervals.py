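"""Coordinate model: intervals, error-region sets, and reference patch plans.

All coordinates are 0-based half-open (BED convention) throughout the
package; conversion to 1-based happens only when writing VCF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence


class ConfigError(ValueError):
    """Malformed region configuration (parse or validation failure)."""


class RegionKind(str, Enum):
    FALSE_DUPLICATION = "FALSE_DUPLICATION"
    COLLAPSED = "COLLAPSED"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("interval contig must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str, label: str | None = None) -> "GenomicInterval":
        """Parse ``contig:start-end`` (0-based half-open)."""
        try:
            contig, span = text.rsplit(":", 1)
            start_s, end_s = span.split("-", 1)
            return cls(contig, int(start_s), int(end_s), label)
        except (ValueError, IndexError) as exc:
            raise ConfigError(f"cannot parse interval {text!r}") from exc


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.contig, iv.start, iv.end)


def normalize_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Sort by (contig, start) and merge overlapping or abutting intervals.

    The label of a merged interval is taken from the first contributing
    interval that carries one.
    """
    ordered = sorted(intervals, key=_sort_key)
    merged: list[GenomicInterval] = []
    for iv in ordered:
        if merged and merged[-1].contig == iv.contig and iv.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.contig,
                prev.start,
                max(prev.end, iv.end),
                prev.label if prev.label is not None else iv.label,
            )
        else:
            merged.append(iv)
    return merged


def covered_bases(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct bases covered by a set of intervals."""
    return sum(len(iv) for iv in normalize_intervals(intervals))


def intersect_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass
class ErrorRegion:
    """One reference error: a falsely duplicated or collapsed locus.

    ``target`` is where corrected calls are wanted; ``mask_intervals`` are
    the extra copies to hard-mask (false duplications only); ``decoy_names``
    name the contigs supplying the missing paralog (collapsed only);
    ``homolog_intervals`` is everywhere reads must be gathered from and must
    cover the target and every mask.
    """

    kind: RegionKind
    target: GenomicInterval
    mask_intervals: list[GenomicInterval] = field(default_factory=list)
    decoy_names: list[str] = field(default_factory=list)
    homolog_intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def label(self) -> str:
        return self.target.label or str(self.target)

    def validate(self) -> None:
        name = self.label
        if self.kind is RegionKind.FALSE_DUPLICATION:
            if not self.mask_intervals:
                raise ConfigError(
                    f"region {name}: FALSE_DUPLICATION requires mask intervals"
                )
            if self.decoy_names:
                raise ConfigError(
                    f"region {name}: FALSE_DUPLICATION must not list decoys"
                )
        elif self.kind is RegionKind.COLLAPSED:
            if not self.decoy_names:
                raise ConfigError(f"region {name}: COLLAPSED requires decoy names")
            if self.mask_intervals:
                raise ConfigError(
                    f"region {name}: COLLAPSED must not list mask intervals"
                )
        required = [self.target, *self.mask_intervals]
        homologs = normalize_intervals(self.homolog_intervals)
        for iv in required:
            if not any(h.contains(iv) for h in homologs):
                raise ConfigError(
                    f"region {name}: homolog intervals must cover {iv}"
                )


@dataclass
class ErrorRegionSet:
    """Validated collection of error regions."""

    regions: list[ErrorRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        for region in self.regions:
            region.validate()

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def all_homolog_intervals(self) -> list[GenomicInterval]:
        """Normalized union of every region's homolog intervals."""
        out: list[GenomicInterval] = []
        for region in self.regions:
            out.extend(region.homolog_intervals)
        return normalize_intervals(out)

    def all_mask_intervals(self) -> list[GenomicInterval]:
        out: list[GenomicInterval] = []
        for region in self.regions:
            out.extend(region.mask_intervals)
        return normalize_intervals(out)

    def targets_by_label(self) -> dict[str, list[GenomicInterval]]:
        return {region.label: [region.target] for region in self.regions}


@dataclass
class PatchPlan:
    """Declarative reference modification: hard-masks plus decoy contigs."""

    base_reference_id: str
    masks: list[GenomicInterval] = field(default_factory=list)
    decoys: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masks = normalize_intervals(self.masks)
        names = [name for name, _ in self.decoys]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate decoy names in patch plan")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "base_reference_id": self.base_reference_id,
            "masks": [
                {"contig": m.contig, "start": m.start, "end": m.end, "label": m.label}
                for m in self.masks
            ],
            "decoys": [{"name": n, "sequence": s} for n, s in self.decoys],
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PatchPlan":
        payload = json.loads(Path(path).read_text())
        masks = [
            GenomicInterval(m["contig"], m["start"], m["end"], m.get("label"))
            for m in payload["masks"]
        ]
        decoys = [(d["name"], d["sequence"]) for d in payload["decoys"]]
        return cls(payload["base_reference_id"], masks, decoys)


# ---------------------------------------------------------------------------
# BED and region-config I/O


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a 3/4-column BED file (0-based half-open, '#' comments ignored)."""
    intervals: list[GenomicInterval] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ConfigError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        try:
            iv = GenomicInterval(
                fields[0],
                int(fields[1]),
                int(fields[2]),
                fields[3] if len(fields) > 3 else None,
            )
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: {exc}") from exc
        intervals.append(iv)
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.contig, str(iv.start), str(iv.end)]
            if iv.label is not None:
                fields.append(iv.label)
            fh.write("\t".join(fields) + "\n")


_CONFIG_COLUMNS = ["contig", "start", "end", "label", "kind", "decoy_names", "masks"]


def read_region_config(
    path: str | Path, homologs_bed: str | Path | None = None
) -> ErrorRegionSet:
    """Read the region-config TSV plus its companion homolog BED.

    Columns: contig, start, end, label, kind, decoy_names (comma list, may
    be empty), masks (comma list of contig:start-end, may be empty).
    Homolog intervals come from ``homologs_bed`` keyed by label; the target
    and masks are always included so the covering invariant holds even with
    a sparse companion file.
    """
    homologs_by_label: dict[str, list[GenomicInterval]] = {}
    if homologs_bed is not None:
        for iv in read_bed(homologs_bed):
            if iv.label is None:
                raise ConfigError(
                    f"{homologs_bed}: homolog intervals need a label column"
                )
            homologs_by_label.setdefault(iv.label, []).append(iv)

    regions: list[ErrorRegion] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ConfigError(
                f"{path}:{lineno}: expected >=5 tab-separated fields "
                f"({', '.join(_CONFIG_COLUMNS)})"
            )
        contig, start_s, end_s, label, kind_s = fields[:5]
        decoy_field = fields[5] if len(fields) > 5 else ""
        mask_field = fields[6] if len(fields) > 6 else ""
        try:
            target = GenomicInterval(contig, int(start_s), int(end_s), label)
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: {exc}") from exc
        try:
            kind = RegionKind(kind_s)
        except ValueError as exc:
            raise ConfigError(
                f"{path}:{lineno}: unknown kind {kind_s!r} "
                f"(expected FALSE_DUPLICATION or COLLAPSED)"
            ) from exc
        decoy_names = [d for d in decoy_field.split(",") if d]
        masks = [
            GenomicInterval.parse(m, label) for m in mask_field.split(",") if m
        ]
        homologs = list(homologs_by_label.get(label, []))
        homologs.append(target)
        homologs.extend(masks)
        region = ErrorRegion(
            kind=kind,
            target=target,
            mask_intervals=normalize_intervals(masks),
            decoy_names=decoy_names,
            homolog_intervals=normalize_intervals(homologs),
        )
        region.validate()
        regions.append(region)
    return ErrorRegionSet(regions)


def write_region_config(
    regions: ErrorRegionSet, path: str | Path, homologs_bed: str | Path
) -> None:
    """Write the TSV + companion homolog BED consumed by read_region_config."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_CONFIG_COLUMNS) + "\n")
        for region in regions:
            t = region.target
            fh.write(
                "\t".join(
                    [
                        t.contig,
                        str(t.start),
                        str(t.end),
                        region.label,
                        region.kind.value,
                        ",".join(region.decoy_names),
                        ",".join(str(m) for m in region.mask_intervals),
                    ]
                )
                + "\n"
            )
    homolog_rows = []
    for region in regions:
        for iv in region.homolog_intervals:
            homolog_rows.append(
                GenomicInterval(iv.contig, iv.start, iv.end, region.label)
            )
    write_bed(homolog_rows, homologs_bed)
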