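"""Simulated knock-in clone experiment and the exact Mann-Whitney test.

Five risk-allele (A/A) and five non-risk (T/T) clones; the risk allele
decreases the skipped-isoform ratio. With complete group separation the
exact two-sided p reaches its 5-vs-5 minimum, 2/252.
"""

from crossld import (
    CloneSimSpec,
    compare_ratio_by_genotype,
    simulate_clones,
    total_expression_test,
)
from crossld.isoforms import skipped_ratio

spec = CloneSimSpec(n_per_genotype=5, baseline_ratio=0.6, effect=-0.4,
                    noise_sd=0.1, seed=1)
table = simulate_clones(spec)
ratios = skipped_ratio(table)
for clone, geno, r in zip(table["clone_id"], table["genotype"], ratios):
    print(f"{clone}  {geno}  skipped/full = {r:.3f}")

comp = compare_ratio_by_genotype(table)
print(f"\nratio test      : U={comp.U:.0f}  p={comp.p_two_sided:.5f} "
      f"({comp.method})")
tot = total_expression_test(table)
print(f"total-output test: U={tot.U:.0f}  p={tot.p_two_sided:.5f}")
print("\nThe ratio differs maximally between genotypes (p = 2/252 "
      "= 0.00794) while total isoform output shows no genotype "
      "association — the variant shifts splicing, not expression.")
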