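"""Two-locus LD from phased haplotypes and from unphased genotypes.

Simulates a panel with a known target r², counts haplotypes directly,
then discards phase and re-estimates the frequencies with EM to show the
two routes agree.
"""

import numpy as np

from crossld import (
    LDTargetSpec,
    hap_freqs_em,
    hap_freqs_phased,
    ld_stats,
    simulate_haplotypes,
)
from crossld.genotype_io import GenotypeMatrix, SampleSet

h = simulate_haplotypes(LDTargetSpec(pA=0.4, pB=0.3, r_signed=0.7,
                                     n_haplotypes=2000, seed=42))
f = hap_freqs_phased(h, "anchor", "satellite")
s = ld_stats(f)
print(f"phased counting : D={s.D:+.4f}  D'={s.Dprime:.4f}  r2={s.r2:.4f}")

# repackage the same haplotypes as unphased diploids
calls = h.haplotypes.reshape(1000, 2, 2).transpose(0, 2, 1).astype(np.int8)
sids = [f"s{i}" for i in range(1000)]
g = GenotypeMatrix(
    list(h.variants),
    SampleSet(sids, {s_: "SIM" for s_ in sids}),
    calls,
    np.zeros((1000, 2), dtype=bool),
)
f_em = hap_freqs_em(g, "anchor", "satellite")
s_em = ld_stats(f_em)
print(f"EM (unphased)   : D={s_em.D:+.4f}  D'={s_em.Dprime:.4f}  "
      f"r2={s_em.r2:.4f}")
print("Target r2 was 0.49; both estimates should sit near it — phase "
      "information is nearly free at this sample size.")
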