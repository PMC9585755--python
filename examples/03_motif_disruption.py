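"""Allele-aware Rbfox motif scan of a variant's sequence context.

The variant sits at the third base of a GCATG word: the A allele
completes the motif, the T allele collapses it.
"""

from crossld import AlleleContext, MotifDef, scan_motifs

ctx = AlleleContext("TTGCATGTT", variant_offset=4, ref="A", alt="T")
for hit in scan_motifs(ctx, [MotifDef()]):
    print(f"motif={hit.motif} start={hit.start} strand={hit.strand} "
          f"variant_base={hit.variant_offset_in_motif} status={hit.status}")
print("\nThe scanner reports the variant at base 3 of the GCATG "
      "instance, present on the reference (A) allele only: the "
      "alternate (T) allele destroys the Rbfox binding word.")
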