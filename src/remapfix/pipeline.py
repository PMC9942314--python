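"""Orchestration of the fix workflow: extract -> re-align -> (splice back).

Each run writes a machine-readable manifest with the resolved parameters,
input checksums, output paths and counters.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pysam

from . import __version__
from .align import BuiltinParams, ExternalBackend, align_pairs, splice_back
from .extract import ExtractionStats, pair_and_dedup, pairs_to_fastq, select_alignments
from .intervals import ErrorRegionSet
from .refpatch import ReferenceSequenceSet


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(
    subcommand: str,
    params: dict,
    inputs: dict[str, str],
    outputs: dict[str, str],
    counters: dict[str, int],
    elapsed: float,
) -> dict:
    missing = [p for p in outputs.values() if not Path(p).exists()]
    if missing:
        raise RuntimeError(f"declared outputs missing at exit: {missing}")
    return {
        "tool": "remapfix",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": params,
        "input_checksums": {k: _md5(v) for k, v in inputs.items()},
        "outputs": outputs,
        "wall_clock_seconds": round(elapsed, 3),
        "counters": counters,
    }


def run_fix(
    bam_path: str | Path,
    regions: ErrorRegionSet,
    patched_ref: ReferenceSequenceSet,
    backend: BuiltinParams | ExternalBackend,
    out_bam: str | Path,
    splice: bool = False,
    rescue_window: int = 1000,
    manifest_path: str | Path | None = None,
) -> dict:
    """Extract affected pairs, re-align them to the patched reference, and
    optionally splice the corrected records back genome-wide.

    Default output is the regional corrected BAM (the fast path); with
    ``splice`` the output is the genome-wide corrected file.
    """
    t0 = time.monotonic()
    stats = ExtractionStats()
    records = select_alignments(bam_path, regions, stats)
    pairs = pair_and_dedup(records, bam_path, rescue_window, stats)

    with pysam.AlignmentFile(str(bam_path)) as aln:
        read_groups = aln.header.to_dict().get("RG", [])

    out_bam = Path(out_bam)
    if splice:
        regional = out_bam.with_suffix(".regional.bam")
    else:
        regional = out_bam
    align_pairs(pairs, patched_ref, backend, regional, read_groups=read_groups)
    counters = {
        "records_selected": stats.selected_records,
        "pairs_emitted": stats.pairs_emitted,
        "pairs_rescued": stats.pairs_rescued,
        "dropped_singletons": stats.dropped_singletons,
        "dropped_ambiguous": stats.dropped_ambiguous,
    }
    outputs = {"corrected_bam": str(out_bam)}
    if splice:
        names = {p.name for p in pairs}
        splice_counters = splice_back(bam_path, regional, names, out_bam)
        counters["records_spliced"] = splice_counters["added"]
        counters["records_removed"] = splice_counters["removed"]
        outputs["regional_bam"] = str(regional)

    manifest = build_manifest(
        subcommand="fix",
        params={
            "splice": splice,
            "rescue_window": rescue_window,
            "backend": backend.__class__.__name__,
        },
        inputs={"bam": str(bam_path)},
        outputs=outputs,
        counters=counters,
        elapsed=time.monotonic() - t0,
    )
    if manifest_path is not None:
        Path(manifest_path).write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


def extract_to_fastq(
    bam_path: str | Path,
    regions: ErrorRegionSet,
    fq1: str | Path,
    fq2: str | Path,
    rescue_window: int = 1000,
) -> ExtractionStats:
    """Extraction-only path: affected pairs to a FASTQ pair."""
    stats = ExtractionStats()
    records = select_alignments(bam_path, regions, stats)
    pairs = pair_and_dedup(records, bam_path, rescue_window, stats)
    pairs_to_fastq(pairs, fq1, fq2)
    return stats
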