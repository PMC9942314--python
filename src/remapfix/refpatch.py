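"""Build the modified reference: hard-mask false duplications, append decoys.

Masking replaces bases with uppercase 'N' (hard masking) so that an aligner
cannot place reads on the extra copy; soft masking would leave the copy
mappable and defeat the purpose. Contig order, names, and lengths are
preserved bit-exactly outside the masked intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .intervals import GenomicInterval, PatchPlan, normalize_intervals

FASTA_WIDTH = 60
_VALID = set("ACGTN")


@dataclass
class ReferenceSequenceSet:
    """Ordered multi-contig reference held in memory (uppercase A/C/G/T/N)."""

    contigs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate contig names in reference")
        for name, seq in self.contigs:
            if not seq:
                raise ValueError(f"contig {name} has empty sequence")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.contigs}

    def sequence(self, name: str) -> str:
        for n, s in self.contigs:
            if n == name:
                return s
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.contigs)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSequenceSet":
        """Read a FASTA file, case-folding sequence to uppercase."""
        path = str(path)
        if not Path(path + ".fai").exists():
            pysam.faidx(path)
        with pysam.FastaFile(path) as fa:
            contigs = [
                (name, fa.fetch(name).upper()) for name in fa.references
            ]
        return cls(contigs)

    def to_fasta(self, path: str | Path, width: int = FASTA_WIDTH) -> None:
        """Write wrapped FASTA and a .fai index sidecar."""
        with open(path, "w") as fh:
            for name, seq in self.contigs:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        pysam.faidx(str(path))


def mask_regions(
    ref: ReferenceSequenceSet, masks: Iterable[GenomicInterval]
) -> ReferenceSequenceSet:
    """Replace the bases inside each mask interval with 'N'.

    Raises ValueError if a mask names a missing contig or exceeds its length.
    Contig names, order, and lengths are unchanged.
    """
    masks = normalize_intervals(masks)
    lengths = ref.lengths
    for m in masks:
        if m.contig not in lengths:
            raise ValueError(f"mask {m} names unknown contig {m.contig!r}")
        if m.end > lengths[m.contig]:
            raise ValueError(
                f"mask {m} exceeds contig length {lengths[m.contig]}"
            )
    by_contig: dict[str, list[GenomicInterval]] = {}
    for m in masks:
        by_contig.setdefault(m.contig, []).append(m)
    out: list[tuple[str, str]] = []
    for name, seq in ref.contigs:
        if name in by_contig:
            chars = list(seq)
            for m in by_contig[name]:
                chars[m.start : m.end] = "N" * len(m)
            seq = "".join(chars)
        out.append((name, seq))
    return ReferenceSequenceSet(out)


def append_decoys(
    ref: ReferenceSequenceSet, decoys: Sequence[tuple[str, str]]
) -> ReferenceSequenceSet:
    """Append decoy contigs after the existing ones, rejecting name clashes."""
    existing = set(ref.names)
    seen: set[str] = set()
    for name, _ in decoys:
        if name in existing or name in seen:
            raise ValueError(f"decoy name {name!r} collides with existing contig")
        seen.add(name)
    return ReferenceSequenceSet(
        list(ref.contigs) + [(n, s.upper()) for n, s in decoys]
    )


def apply_patch(ref: ReferenceSequenceSet, plan: PatchPlan) -> ReferenceSequenceSet:
    """Mask then append decoys; deterministic, input untouched."""
    return append_decoys(mask_regions(ref, plan.masks), plan.decoys)
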