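"""Build a patched reference: hard-mask a false duplication and append a
missing paralog as a decoy contig.

The patch never changes contig order or lengths: masked bases become 'N'
so an aligner cannot place reads on the extra copy, and the decoy gives
reads from the missing paralog a home of their own.
"""

from remapfix import GenomicInterval, PatchPlan, ReferenceSequenceSet, apply_patch

ref = ReferenceSequenceSet(
    [
        ("chr1", "ACGTACGTACGTACGTACGT"),
        ("chr2", "TTGGCCAATTGGCCAATTGG"),
    ]
)
plan = PatchPlan(
    base_reference_id="toy",
    masks=[GenomicInterval("chr2", 4, 12)],
    decoys=[("kcnj18_decoy", "GATTACAGATTACA")],
)
patched = apply_patch(ref, plan)

for name, seq in patched.contigs:
    print(f"{name:>14}  {seq}")
print()
print("chr2 keeps its length; bases 4-12 are hard-masked to N;")
print("the decoy contig is appended after all original contigs.")
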