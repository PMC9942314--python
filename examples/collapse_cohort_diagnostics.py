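"""Collapsed-duplication diagnostics on a simulated cohort.

Two real paralogs (1% diverged) are represented by a single reference
copy. Reads from the missing paralog pile onto the kept copy: depth
doubles and every paralog-distinguishing site (PSV) looks like a ~50%
heterozygote in every sample, driving the per-site inbreeding coefficient
F = 1 - H_obs/H_exp to -1. Appending the missing paralog as a decoy contig
normalizes both, at the documented cost of some mapping quality.
"""

from remapfix.bench import collapse_config, run_scenario

# 4 samples keep the example quick; the acceptance run uses 10
result = run_scenario(collapse_config(seed=1, n_samples=4))

pre, post = result.pre_benchmark, result.post_benchmark
post_f = result.post_median_f_psv if result.post_median_f_psv is not None else 0.0
print(f"samples: {result.n_samples}, PSVs: {result.n_psv}")
print()
print(f"{'':>28} {'before fix':>11} {'after fix':>11}")
print(f"{'depth ratio vs flanks':>28} {result.pre_depth_ratio:>11.2f} "
      f"{result.post_depth_ratio:>11.2f}")
print(f"{'median F at PSV sites':>28} {result.pre_median_f_psv:>11.2f} "
      f"{post_f:>11.2f}")
print(f"{'false-het calls per PSV':>28} {result.pre_psv_het_frac:>11.2f} "
      f"{result.post_psv_het_frac:>11.2f}")
print(f"{'SNV precision':>28} {pre.precision:>11.3f} {post.precision:>11.3f}")
print(f"{'SNV recall':>28} {pre.recall:>11.3f} {post.recall:>11.3f}")
print(f"{'mean MAPQ in target':>28} {result.pre_mean_mapq:>11.1f} "
      f"{result.post_mean_mapq:>11.1f}")
print()
print("F near -1 with doubled depth is the collapse fingerprint; the decoy")
print("removes the spurious heterozygotes (precision jumps) while recall of")
print("real variants, including those on the restored paralog, is preserved.")
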