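# Methods

## The two error classes and their repair

A **false duplication** is an extra, near-identical reference copy of a
locus that real genomes carry once. An aligner splits the locus's reads
between the copies: each multi-mapping read receives MAPQ 0 (by the
convention that MAPQ 0 marks multiple equally good placements), depth over
either copy falls toward half of the genome-wide mean, and variant callers
— which discard MAPQ-0 reads — lose the heterozygous variants in the
region. Reads whose variant allele happens to match the false copy are
placed there *confidently*, so those variants vanish even where some reads
still map uniquely; this allele-stealing also produces an excess of
homozygous calls (heterozygote deficiency, positive inbreeding
coefficients). The repair is to hard-mask the extra copy with `N`
(soft-masking would leave it mappable) and re-align the affected reads.

A **collapsed duplication** is the mirror error: two real paralogs,
diverged by some rate *d*, share a single reference copy. Reads from the
missing paralog land on the kept copy carrying their paralog-distinguishing
variants (PSVs); depth doubles, and each PSV appears as a ~50%
allele-fraction heterozygote in essentially every sample — a cohort-wide
heterozygote excess (inbreeding coefficient near −1) that true variation
cannot produce. The repair appends the missing paralog as a decoy contig.
The documented cost: reads that do not span a PSV become ambiguous between
copy and decoy, so mean MAPQ in the target *drops* after the fix while the
false heterozygotes disappear.

The pipeline operates regionally: read pairs are selected from the
existing coordinate-sorted BAM over the union of intervals homologous to
the affected loci, with exclusion flag mask 2316 (unmapped, mate-unmapped,
secondary, supplementary); duplicate-flagged and QC-fail records are
retained because downstream callers can filter them. Pairs are
reconstituted under unique read names; a singleton whose mate sits within
`rescue_window` (default 1000 bp, same contig) of it is completed by
fetching the mate at its recorded position, and remaining singletons,
names with more than two primary records, or duplicated same-mate names
are dropped and counted. Re-aligned records can replace the originals
genome-wide ("splice-back"), with removal by read name across the whole
file so no orphaned secondary/supplementary records survive.

## The builtin mapper

A test-grade, ungapped seed-and-extend mapper keeps the whole pipeline
runnable without external binaries. Exact k-mers (k = 21, sampled every
5 bp of the read, both strands) are looked up in a full-reference index;
seeds sharing a diagonal define candidate loci; each candidate is scored
over the full read (match +1, mismatch −4, candidates with non-positive
score or overhanging a contig end are discarded). MAPQ is 0 on a score
tie, otherwise `min(60, 6·(best − second-best))`, with second-best taken
as 0 when no alternative candidate exists. This formula is this package's
own; the property that matters downstream is only that multi-placement
reads get MAPQ 0.

Pair placement considers, for each mate, candidates within one
substitution (score 5) of its personal best, and selects the compatible
combination — same contig, opposite strands, implied insert inside the
configured window — with the highest summed score; this is how a tied or
slightly suboptimal mate is "rescued" next to its partner, with its MAPQ
recomputed after the pairing excludes incompatible ties. When several
compatible combinations tie, both mates get MAPQ 0 and the placement is
chosen deterministically (lowest contig index, then coordinate, then
strand) or, with `random_ties`, by a seeded generator — the latter is what
reproduces the realistic 50/50 depth split over a false duplication.

`pair_aware=False` disables joint placement entirely (each mate placed
independently). The simulation harness uses this mode when emulating the
*upstream* whole-genome aligner that produced the input BAM, because joint
placement lets one PSV-spanning mate resolve its partner and would leave
only ~50–65% of duplicated-locus reads at MAPQ 0; the per-read expectation
`(1−d)^ℓ ≈ 0.82` at d = 0.002, ℓ = 100 — the regime the diagnostics are
designed for — requires per-read independence. The *fix* path always uses
proper pair rescue.

External aligners plug in through a command template with `{ref}`, `{fq1}`,
`{fq2}` placeholders producing SAM on stdout, executed without a shell;
the output header is validated against the patched reference and the
result is coordinate-sorted and indexed.

## Genotyper and comparator

The pileup genotyper counts bases from records passing the extraction
flag mask with MAPQ ≥ 20 and base quality ≥ 13 (thresholds in the range
production callers use for pre-filtering). At each non-masked reference
position with depth ≥ 4, the most frequent non-reference base with
fraction *f* yields a heterozygous call for 0.2 ≤ *f* ≤ 0.8 and a
homozygous-alternate call above. SNVs only: the mapper is ungapped, so
indel calling is delegated to external tools through the backend contract.
pysam's pileup engine does not apply `min_mapping_quality` under the
stepper used here, so both quality filters are enforced explicitly per
pileup read.

The comparator matches truth records exactly on (contig, position, ref,
alt, genotype) after restriction of both sets to confident regions;
genotype mismatches count as FP + FN. This is deliberately stricter than
haplotype-aware benchmarking tools — adequate for simulated SNV truth
sets, and biased, if anywhere, against the method under test.

## The simulator

Each scenario builds a truth genome and an erroneous reference over random
uniform-composition sequence:

* `FALSE_DUP`: truth has `chrA = flank + locus + flank`; the reference
  additionally carries `chrB` whose central segment is the locus with
  exactly `round(d·w)` substitutions (d = `paralog_divergence`) placed
  uniformly over the locus interior `w`, at least two read lengths from
  the edges so every PSV is coverable by fully-internal reads. The patch
  plan masks the `chrB` copy.
* `COLLAPSE`: truth has both `chrA` and `chrB` (the diverged paralog with
  its own flanks); the reference has only `chrA`. The patch plan appends
  the whole missing contig as a decoy, and truth variants on the paralog
  are expressed in decoy coordinates.
* `CLEAN`: truth equals reference; empty patch plan.

The PSV count is deterministic rather than Bernoulli so the realized
divergence equals the configured rate — the diagnostic expectations above
are computed from the rate, and a ±2 SD draw would dominate them at these
locus sizes.

Diploid samples carry heterozygous SNVs on one haplotype at
`het_snv_rate` per bp (default 10⁻³, the human heterozygosity scale),
placed in the locus interior away from PSV positions. In `FALSE_DUP`,
each PSV site is additionally a genuine heterozygous site of the sample
with probability `dup_psv_het_fraction` (default 0.5), with the alternate
allele equal to the false copy's base — modelling that the extra copy
typically originated from alternate haplotype sequence, and producing the
read-stealing variant loss described above. PSV positions are always
recorded separately from sample variants.

Reads: fragment length ~ Normal(`insert_mean` = 350, `insert_sd` = 50)
truncated below at the read length; fragment start uniform per contig;
mate 1 from the forward end, mate 2 reverse-complemented from the other;
per-base substitution errors at `base_error_rate`; pair count set so
expected depth equals `coverage`. All draws flow from one integer seed
through documented child streams (sequence, PSVs, per-sample SNVs,
per-sample reads), so a bundle is byte-reproducible; the PSV stream is
re-drawable independently of the builder.

What the generator does *not* model: indels (the builtin mapper is
ungapped), quality-score error profiles, GC/coverage bias, more than two
copies, partial-overlap duplications, or population structure across
samples (each sample's variants are drawn independently). Passing tests
therefore demonstrate the mechanics of the error classes and their repair,
not performance on real sequencing artefacts.

## Measurement conventions

* MAPQ-0 fractions are counted over the interiors (one read length inside
  each end) of the target *and* any extra copy: a tied read lands on
  either copy, so counting a single copy would halve the apparent
  multi-mapping fraction.
* Depth is measured over the target interior only (every overlapping read
  fully internal, no flank anchoring) and divided by the mean depth over
  baseline intervals on both unique flanks, kept one maximum fragment
  length away from contig ends to avoid edge coverage dips.
* Cohort inbreeding coefficients use the plain single-population
  estimator `F = 1 − H_obs/H_exp` from called genotypes, with uncalled
  samples at a called site counted as homozygous reference and `F`
  undefined at monomorphic sites. The post-fix "median F over PSV sites"
  is taken over PSV sites that still receive any non-reference genotype;
  when none does, the departure is zero by construction and 0.0 is
  reported.
* Variant metrics aggregate counts over all simulated samples (3 for the
  false-duplication run, 10 for the collapse run) before computing
  recall/precision; per-sample recalls over a handful of variants are too
  granular to be stable.

## Scale and numerical choices

Default problem sizes — 5 kb loci, 3 kb flanks, 40× coverage, up to 10
samples — make the full simulate→fix→benchmark cycle run in seconds to
tens of seconds in pure Python/numpy; these sizes are large enough that
the depth and MAPQ expectations concentrate (binomial SDs of a few
percent) while every brute-force oracle in the test suite stays exact.
Tie-breaks are everywhere deterministic unless seeded randomness is
requested; sorting and FASTA/VCF emission avoid timestamps so repeated
runs are byte-identical. Interval arithmetic is 0-based half-open
throughout, with 1-based conversion only at the VCF boundary; abutting
intervals merge, since masking and fetching semantics are unaffected.

## Known limitations

* Regional re-alignment trusts the provided homolog intervals; reads
  mis-mapped *outside* them are never revisited (mirrored by the mate
  rescue policy, which drops pairs whose mate lies farther than the
  rescue window rather than chasing discordant placements).
* The builtin mapper's substitution-only model means indel-bearing reads
  map with mismatches or not at all; real data should use an external
  backend.
* The genotyper has no statistical genotype likelihoods; its fixed
  allele-fraction bands are adequate at 40× but would miscall at low
  depth.
* Decoy contigs carry no annotation; their provenance lives only in the
  FASTA description line.
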