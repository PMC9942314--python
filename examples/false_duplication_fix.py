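"""End-to-end false-duplication repair on simulated data.

A 5 kb locus that exists once in the genome appears twice (0.2% diverged)
in the reference: reads split between the copies, mapping quality drops to
zero for most of them, depth halves, and heterozygous SNVs go uncalled.
Masking the extra copy and re-aligning only the affected read pairs
restores all three signatures.
"""

from remapfix.bench import false_dup_config, run_scenario

result = run_scenario(false_dup_config(seed=1))

pre, post = result.pre_benchmark, result.post_benchmark
print(f"samples: {result.n_samples}, truth het SNVs: {result.n_truth_variants}, "
      f"copy-distinguishing sites (PSVs): {result.n_psv}")
print()
print(f"{'':>24} {'before fix':>12} {'after fix':>12}")
print(f"{'MAPQ-0 read fraction':>24} {result.pre_frac_mapq0:>12.3f} "
      f"{result.post_frac_mapq0:>12.3f}")
print(f"{'depth ratio vs flanks':>24} {result.pre_depth_ratio:>12.2f} "
      f"{result.post_depth_ratio:>12.2f}")
print(f"{'SNV recall':>24} {pre.recall:>12.3f} {post.recall:>12.3f}")
print(f"{'SNV precision':>24} "
      f"{pre.precision if pre.precision is not None else float('nan'):>12.3f} "
      f"{post.precision:>12.3f}")
print()
print("Before the fix, ties between the two copies scatter reads (MAPQ 0,")
print("half depth) and variant-carrying reads matching the false copy are")
print("stolen by it, so recall collapses; after masking, every read has a")
print("unique home and the heterozygous SNVs are recovered.")
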