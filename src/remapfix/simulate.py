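"""Synthetic truth genomes, erroneous references, reads, and truth VCFs.

Two reference error classes are generated:

* ``FALSE_DUP`` — the truth genome carries ONE copy of a locus but the
  reference carries two (the second diverged by ``paralog_divergence``);
  the patch plan hard-masks the extra copy.
* ``COLLAPSE`` — the truth genome carries TWO diverged paralogs but the
  reference carries only one; the patch plan appends the missing paralog
  (with its flanks) as a decoy contig.

``CLEAN`` produces truth == reference with an empty patch plan. Diploid
samples carry heterozygous SNVs planted on one haplotype; paralogous
sequence variants (PSVs) are recorded separately from sample variants.
All randomness flows from one integer seed through documented child
streams, so identical config + seed reproduces a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .extract import ReadPair, pairs_to_fastq, revcomp
from .intervals import (
    ErrorRegion,
    ErrorRegionSet,
    GenomicInterval,
    PatchPlan,
    RegionKind,
    write_bed,
    write_region_config,
)
from .refpatch import ReferenceSequenceSet, apply_patch
from .smallvar import VariantCall, write_vcf

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: child-stream ids: sequence material, PSV placement, per-sample SNVs, reads
STREAM_SEQUENCE = 0
STREAM_PSV = 1
STREAM_SNV_BASE = 10
STREAM_READS_BASE = 1000


@dataclass
class SimulationConfig:
    scenario: str  # FALSE_DUP | COLLAPSE | CLEAN
    seed: int = 0
    flank_length: int = 3000
    locus_length: int = 5000
    paralog_divergence: float = 0.01
    het_snv_rate: float = 0.001
    coverage: float = 40.0
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    base_error_rate: float = 0.002
    n_samples: int = 1
    #: FALSE_DUP only: probability that a copy-distinguishing site is a real
    #: heterozygous site of the sample whose alternate allele equals the
    #: false copy's base — the mechanism by which the extra copy steals
    #: variant-carrying reads and erases the call.
    dup_psv_het_fraction: float = 0.5

    def validate(self) -> None:
        if self.scenario not in ("FALSE_DUP", "COLLAPSE", "CLEAN"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("paralog_divergence", "het_snv_rate", "base_error_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.dup_psv_het_fraction <= 1.0:
            raise ValueError("dup_psv_het_fraction must lie in [0, 1]")
        if self.read_length >= self.insert_mean:
            raise ValueError("read_length must be below insert_mean")
        if self.locus_length < 10 * self.read_length:
            raise ValueError("locus_length must be >= 10 * read_length")
        if self.coverage < 0 or self.n_samples < 1:
            raise ValueError("coverage must be >= 0 and n_samples >= 1")

    @property
    def samples(self) -> list[str]:
        return [f"s{i:02d}" for i in range(self.n_samples)]

    def insert_window(self) -> tuple[int, int]:
        lo = max(self.read_length, int(self.insert_mean - 4 * self.insert_sd))
        return lo, int(self.insert_mean + 4 * self.insert_sd)


@dataclass
class SimulatedTruth:
    config: SimulationConfig
    truth_ref: ReferenceSequenceSet
    err_ref: ReferenceSequenceSet
    patch_plan: PatchPlan
    regions: ErrorRegionSet
    truth_variants: dict[str, list[VariantCall]]
    psv_sites: list[tuple[str, int, str, str]]
    baseline: list[GenomicInterval]
    confident: list[GenomicInterval]
    sample_haplotypes: dict[str, dict[str, tuple[str, str]]] = field(repr=False, default_factory=dict)

    @property
    def patched_ref(self) -> ReferenceSequenceSet:
        return apply_patch(self.err_ref, self.patch_plan)

    def interior_targets(self) -> dict[str, list[GenomicInterval]]:
        """Target intervals shrunk by one read length on each side, so every
        read overlapping them is fully internal to the locus; this is the
        region over which the depth signature is measured free of
        flank-anchoring edge effects."""
        rl = self.config.read_length
        out: dict[str, list[GenomicInterval]] = {}
        for region in self.regions:
            t = region.target
            out[region.label] = [
                GenomicInterval(t.contig, t.start + rl, t.end - rl, t.label)
            ]
        return out

    def mapq_regions(self) -> dict[str, list[GenomicInterval]]:
        """Intervals over which multi-mapping (MAPQ 0) reads are counted:
        the interiors of the target and of every extra copy, since ties
        scatter reads over all copies of a false duplication."""
        rl = self.config.read_length
        out: dict[str, list[GenomicInterval]] = {}
        for region in self.regions:
            ivs = []
            for iv in [region.target, *region.mask_intervals]:
                ivs.append(GenomicInterval(iv.contig, iv.start + rl, iv.end - rl,
                                           region.label))
            out[region.label] = ivs
        return out


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(BASES, size=n).tobytes().decode("ascii")


def draw_psv_positions(config: SimulationConfig) -> np.ndarray:
    """Locus-relative PSV positions.

    Exactly ``round(paralog_divergence * window)`` positions are drawn
    uniformly without replacement over the locus interior, at least two
    read lengths from either edge, so the realized divergence matches the
    configured rate instead of fluctuating around it. This is the public
    generator contract (seed stream ``STREAM_PSV``), reproducible
    independently of the full builder.
    """
    pad = 2 * config.read_length
    rng = _rng(config.seed, STREAM_PSV)
    window = config.locus_length - 2 * pad
    n_psv = int(round(config.paralog_divergence * window))
    positions = rng.choice(window, size=min(n_psv, window), replace=False)
    return np.sort(positions) + pad


def _mutate(seq: str, positions: np.ndarray, rng: np.random.Generator) -> str:
    chars = list(seq)
    for p in positions:
        current = chars[p]
        options = [b for b in "ACGT" if b != current]
        chars[p] = options[int(rng.integers(3))]
    return "".join(chars)


def build_truth_and_reference(config: SimulationConfig) -> SimulatedTruth:
    """Construct truth genome, erroneous reference, patch plan and truth
    variants for the configured scenario."""
    config.validate()
    fl, L, rl = config.flank_length, config.locus_length, config.read_length
    seq_rng = _rng(config.seed, STREAM_SEQUENCE)
    flanks = [_random_seq(seq_rng, fl) for _ in range(4)]
    locus = _random_seq(seq_rng, L)
    chr_a = flanks[0] + locus + flanks[1]
    target = GenomicInterval("chrA", fl, fl + L, None)
    pad_iv = GenomicInterval("chrA", max(0, fl - rl), fl + L + rl)

    psv_rel = draw_psv_positions(config)
    psv_rng = _rng(config.seed, STREAM_PSV + 100)  # alt-base stream
    copy2 = _mutate(locus, psv_rel, psv_rng)
    chr_b = flanks[2] + copy2 + flanks[3]
    psv_sites = [
        ("chrA", fl + int(p), locus[int(p)], copy2[int(p)]) for p in psv_rel
    ]

    # baseline on both unique flanks, clear of the homolog padding and of
    # contig-edge coverage dips (margin = largest simulated fragment)
    margin = int(config.insert_mean + 4 * config.insert_sd)
    baseline = [
        GenomicInterval("chrA", margin, fl - 2 * rl),
        GenomicInterval("chrA", fl + L + 2 * rl, 2 * fl + L - margin),
    ]

    if config.scenario == "CLEAN":
        truth_contigs = [("chrA", chr_a)]
        err_contigs = [("chrA", chr_a)]
        plan = PatchPlan("sim_ref", [], [])
        regions = ErrorRegionSet([])
        confident = [GenomicInterval("chrA", fl, fl + L)]
        psv_sites = []
    elif config.scenario == "FALSE_DUP":
        truth_contigs = [("chrA", chr_a)]
        err_contigs = [("chrA", chr_a), ("chrB", chr_b)]
        mask = GenomicInterval("chrB", fl, fl + L, "dup1")
        plan = PatchPlan("sim_ref", [mask], [])
        regions = ErrorRegionSet(
            [
                ErrorRegion(
                    kind=RegionKind.FALSE_DUPLICATION,
                    target=GenomicInterval("chrA", fl, fl + L, "dup1"),
                    mask_intervals=[mask],
                    homolog_intervals=[
                        GenomicInterval("chrA", pad_iv.start, pad_iv.end, "dup1"),
                        GenomicInterval("chrB", max(0, fl - rl), fl + L + rl, "dup1"),
                    ],
                )
            ]
        )
        confident = [GenomicInterval("chrA", fl, fl + L)]
    else:  # COLLAPSE
        truth_contigs = [("chrA", chr_a), ("chrB", chr_b)]
        err_contigs = [("chrA", chr_a)]
        plan = PatchPlan("sim_ref", [], [("chrB", chr_b)])
        regions = ErrorRegionSet(
            [
                ErrorRegion(
                    kind=RegionKind.COLLAPSED,
                    target=GenomicInterval("chrA", fl, fl + L, "col1"),
                    decoy_names=["chrB"],
                    homolog_intervals=[
                        GenomicInterval("chrA", pad_iv.start, pad_iv.end, "col1")
                    ],
                )
            ]
        )
        confident = [
            GenomicInterval("chrA", fl, fl + L),
            GenomicInterval("chrB", fl, fl + L),
        ]

    truth_ref = ReferenceSequenceSet(truth_contigs)
    err_ref = ReferenceSequenceSet(err_contigs)

    psv_by_contig = {"chrA": {fl + int(p) for p in psv_rel}}
    if config.scenario == "COLLAPSE":
        psv_by_contig["chrB"] = {fl + int(p) for p in psv_rel}

    truth_variants: dict[str, list[VariantCall]] = {}
    sample_haplotypes: dict[str, dict[str, tuple[str, str]]] = {}
    pad = 2 * rl
    for si, sample in enumerate(config.samples):
        snv_rng = _rng(config.seed, STREAM_SNV_BASE + si)
        variants: list[VariantCall] = []
        haps: dict[str, tuple[str, str]] = {}
        for contig, seq in truth_contigs:
            window = np.flatnonzero(
                snv_rng.random(L - 2 * pad) < config.het_snv_rate
            ) + (fl + pad)
            forbidden = psv_by_contig.get(contig, set())
            positions = [int(p) for p in window if int(p) not in forbidden]
            hap2 = list(seq)
            for p in positions:
                ref_base = seq[p]
                options = [b for b in "ACGT" if b != ref_base]
                alt = options[int(snv_rng.integers(3))]
                hap2[p] = alt
                variants.append(VariantCall(contig, p, ref_base, alt, "het"))
            if config.scenario == "FALSE_DUP" and contig == "chrA":
                # the sample is heterozygous at a fraction of the sites that
                # distinguish the kept copy from the false one, carrying the
                # false copy's allele — those reads get stolen by the copy
                for c, p, ref_base, alt in psv_sites:
                    if snv_rng.random() < config.dup_psv_het_fraction:
                        hap2[p] = alt
                        variants.append(VariantCall(c, p, ref_base, alt, "het"))
            haps[contig] = (seq, "".join(hap2))
        variants.sort(key=lambda v: (v.contig, v.pos))
        truth_variants[sample] = variants
        sample_haplotypes[sample] = haps

    return SimulatedTruth(
        config=config,
        truth_ref=truth_ref,
        err_ref=err_ref,
        patch_plan=plan,
        regions=regions,
        truth_variants=truth_variants,
        psv_sites=psv_sites,
        baseline=baseline,
        confident=confident,
        sample_haplotypes=sample_haplotypes,
    )


@dataclass
class TruePlacement:
    name: str
    contig: str
    start: int
    fragment_length: int
    haplotype: int


def simulate_reads(
    sim: SimulatedTruth, sample: str
) -> tuple[list[ReadPair], list[TruePlacement]]:
    """Paired-end reads with substitution errors from one diploid sample.

    Fragment starts are uniform over each contig, fragment lengths
    Normal(insert_mean, insert_sd) truncated below at read_length; mate 1
    reads the forward end, mate 2 the reverse complement of the other end.
    Expected total depth equals ``coverage``; deterministic given the seed.
    """
    config = sim.config
    rl = config.read_length
    si = config.samples.index(sample)
    rng = _rng(config.seed, STREAM_READS_BASE + si)
    pairs: list[ReadPair] = []
    placements: list[TruePlacement] = []
    qual = "I" * rl
    for contig, (hap1, hap2) in sorted(sim.sample_haplotypes[sample].items()):
        n = len(hap1)
        n_pairs = int(round(config.coverage * n / (2 * rl)))
        for i in range(n_pairs):
            hap = int(rng.integers(2))
            top = hap1 if hap == 0 else hap2
            frag = int(np.clip(round(rng.normal(config.insert_mean, config.insert_sd)), rl, n))
            start = int(rng.integers(0, n - frag + 1))
            m1 = top[start : start + rl]
            m2 = revcomp(top[start + frag - rl : start + frag])
            if config.base_error_rate > 0:
                m1 = _add_errors(m1, rng, config.base_error_rate)
                m2 = _add_errors(m2, rng, config.base_error_rate)
            name = f"{sample}_{contig}_{i:06d}"
            pairs.append(ReadPair(name, (m1, qual), (m2, qual)))
            placements.append(TruePlacement(name, contig, start, frag, hap))
    return pairs, placements


def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for p in np.flatnonzero(mask):
        current = chars[p]
        options = [b for b in "ACGT" if b != current]
        chars[p] = options[int(rng.integers(3))]
    return "".join(chars)


MANIFEST_SCHEMA_VERSION = 1


def write_bundle(sim: SimulatedTruth, out_dir: str | Path) -> dict[str, str]:
    """Write the full simulation bundle; returns {role: path}.

    Files: truth_ref.fasta, err_ref.fasta, patched_ref.fasta,
    patch_plan.json, regions.tsv + homologs.bed, baseline.bed,
    confident.bed, psv.tsv, reads_<sample>_R1/R2.fastq,
    truth.<sample>.vcf, manifest.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(role: str, name: str) -> Path:
        paths[role] = str(out / name)
        return out / name

    sim.truth_ref.to_fasta(_p("truth_ref", "truth_ref.fasta"))
    sim.err_ref.to_fasta(_p("err_ref", "err_ref.fasta"))
    sim.patched_ref.to_fasta(_p("patched_ref", "patched_ref.fasta"))
    sim.patch_plan.to_json(_p("patch_plan", "patch_plan.json"))
    write_region_config(
        sim.regions, _p("regions", "regions.tsv"), _p("homologs", "homologs.bed")
    )
    write_bed(sim.baseline, _p("baseline", "baseline.bed"))
    write_bed(sim.confident, _p("confident", "confident.bed"))
    with open(_p("psv", "psv.tsv"), "w") as fh:
        for contig, pos, ref, alt in sim.psv_sites:
            fh.write(f"{contig}\t{pos}\t{ref}\t{alt}\n")

    patched_lengths = sim.patched_ref.lengths
    truth_lengths = sim.truth_ref.lengths
    for sample in sim.config.samples:
        pairs, _ = simulate_reads(sim, sample)
        pairs_to_fastq(
            pairs,
            _p(f"reads_{sample}_R1", f"reads_{sample}_R1.fastq"),
            _p(f"reads_{sample}_R2", f"reads_{sample}_R2.fastq"),
        )
        contigs = {
            name: truth_lengths.get(name, patched_lengths.get(name, 0))
            for name in sorted(
                {v.contig for v in sim.truth_variants[sample]} | set(truth_lengths)
            )
        }
        write_vcf(
            sim.truth_variants[sample],
            contigs,
            _p(f"truth_{sample}", f"truth.{sample}.vcf"),
            sample=sample,
        )

    manifest = {
        "schema_version": MANIFEST_SCHEMA_VERSION,
        "config": dataclasses.asdict(sim.config),
        "seed": sim.config.seed,
        "files": {role: Path(p).name for role, p in sorted(paths.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    paths["manifest"] = str(out / "manifest.json")
    return paths
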