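"""Shared fixtures: tiny references and programmatically built BAM files."""

from __future__ import annotations

import random

import pysam
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_sequence(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_bam(path, contigs: dict[str, int], records: list[dict]) -> str:
    """Write a coordinate-sorted, indexed BAM from record dicts.

    Each record dict: name, flag, contig, pos, mapq, cigar, seq (optional;
    a run of 'A' matching the CIGAR read length is used if missing),
    next_contig/next_pos (optional), tags (optional list of tuples).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contigs.items()],
    }
    path = str(path)
    unsorted = path + ".unsorted.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as out:
        for spec in records:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = spec["name"]
            seg.flag = spec["flag"]
            seg.reference_id = out.header.get_tid(spec["contig"])
            seg.reference_start = spec["pos"]
            seg.mapping_quality = spec.get("mapq", 60)
            seg.cigarstring = spec.get("cigar", "10M")
            read_len = seg.infer_query_length() or 10
            seq = spec.get("seq", "A" * read_len)
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if "next_contig" in spec:
                seg.next_reference_id = out.header.get_tid(spec["next_contig"])
                seg.next_reference_start = spec["next_pos"]
            for tag, value in spec.get("tags", []):
                seg.set_tag(tag, value)
            out.write(seg)
    pysam.sort("--no-PG", "-o", path, unsorted)
    pysam.index(path)
    return path


@pytest.fixture
def tmp_bam_factory(tmp_path):
    counter = {"n": 0}

    def factory(contigs, records):
        counter["n"] += 1
        return make_bam(tmp_path / f"toy{counter['n']}.bam", contigs, records)

    return factory
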