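# Methods

## Scope and model

`crossld` treats the nomination of a shared primary functional variant
as deterministic set algebra on pairwise LD, followed by mechanistic
annotation. There is no probabilistic fine-mapping (no posteriors, no
credible sets): a variant is a candidate for a trait when its r² with
that trait's GWAS-lead variant strictly exceeds a threshold, and it is
*shared* when it is a candidate for every trait. The approach assumes
the traits' causal signals colocalise in the locus and that r² against
the leads, computed on a reference panel that matches the GWAS discovery
ancestries, is an adequate proxy for signal membership.

## Two-locus LD

Haplotype frequencies are the primitive. With phased haplotypes they
are direct counts. With unphased diploid genotypes they are estimated
by EM over the four haplotype frequencies, in which the nine two-locus
genotype classes decompose uniquely except the double heterozygote,
split each E-step between its two phasings in proportion to
`p_AB·p_ab` vs `p_Ab·p_aB`. Choices:

* **Initialisation at linkage equilibrium** (`p_AB = p_A·p_B` from the
  genotype marginals). This makes the estimate deterministic and
  resolves the degenerate all-double-heterozygote input — whose
  likelihood has two symmetric maxima — at the equilibrium fixed point
  rather than an arbitrary one.
* **Convergence**: maximum absolute frequency change < 1e-8, iteration
  cap 1000; non-convergence raises an error that carries the last
  estimate. The EM preserves the allele-frequency marginals exactly, so
  the only free parameter is `p_AB`; tests verify the fixed point
  against direct likelihood maximisation over that parameter.
* **Missing genotypes** are handled pairwise complete-case: an
  individual is dropped only for pairs where it lacks a call.
* **Undefined LD** (a monomorphic locus makes the r² denominator zero)
  propagates as a flagged undefined value, never silently dropped, and
  can never pass a candidacy threshold.

`D′` is capped at 1 and `r²` at 1 to absorb floating-point overshoot;
the invariant `r² ≤ D′²` is property-tested on random frequency
vectors.

## Pooled multi-population panels

"Combined" LD across ancestries is computed by concatenating the
haplotypes of the population panels into one panel before counting —
i.e. populations are weighted by their haplotype counts, not averaged
per population. This mirrors how multi-population reference-panel
lookups concatenate samples. Per-population profiles remain available
for concordance checks (which population shows the higher r² with a
shared candidate).

## Candidate sets and intersection

The threshold comparison is **strict** (`r² > 0.2` by default):
boundary values are excluded. The lead variant always belongs to its
own candidate set (self-r² = 1). Intersection is over all leads;
output ordering is genomic position then identifier, and display
rounding is 4 decimals with raw precision retained in JSON. A lead
absent from the genotype panel is a hard error — substituting a proxy
would silently change the analysis. The locus window is a configuration
knob, not a constant: analyses of real data must document their window.

## Motif scanning

Motifs are exact IUPAC words (default Rbfox, DNA `GCATG` for the RNA
word `GCAUG`), scanned on both strands of the variant's sequence
context with overlap-aware regex matching; no PWM scoring. For each
allele's sequence, every instance overlapping the variant is located;
instances are paired across alleles by (start, strand) and classified
`destroyed` (reference allele only), `created` (alternate only) or
`retained` (both — possible at degenerate pattern positions). The
variant's offset within a motif is reported 1-based along the motif's
own 5′→3′ direction, so a variant at the third base of a plus-strand
GCATG reads "3". Which allele letter is the disease-risk allele is an
interpretation layered on top (the motif-completing allele is reported
as such); the scanner itself makes no risk claim.

## Transcript models and translation

Exons are 0-based half-open genomic intervals ordered 5′→3′; the CDS is
transcript-relative and includes the stop codon. A skip event removes a
full exon or a genomic sub-interval within one exon; CDS coordinates
are re-derived by subtracting removed bases upstream of and inside the
coding span. The surviving CDS is translated (standard code, Biopython)
from the original ATG to the first stop, scanning past the bookkept CDS
end into downstream sequence so a frameshift-induced premature stop —
or read-through — is found where it actually occurs. Frame preservation
is exactly `removed coding length ≡ 0 (mod 3)`; `aa_deleted` is
reported only when the frame is preserved; a stop upstream of where the
full-length stop maps is flagged as a premature termination codon.

## Exact Mann–Whitney U

Two-sided p is defined symmetrically: the probability, over all
`C(nA+nB, nA)` equally likely group assignments of the pooled values
(midranks for ties), that `|U − nA·nB/2|` is at least the observed
deviation. Complete enumeration is used up to `nA + nB = 20` — the
5-vs-5 clone design demands exactness and enumeration is cheap there —
and the tie-corrected normal approximation with a continuity correction
of 1/2 beyond. On tie-free data the symmetric-tail definition coincides
with the doubled-tail definition (the null distribution of U is
symmetric); with ties they can differ, and the enumeration is the
definition. The primary outcome measure is
`(partial-skip + full-skip) / full-length` per clone (full-length in the
denominator); `skipped/(skipped+full)` is provided as a clearly labelled
secondary measure. RT-PCR calibration is not modelled: abundances are
taken as given molarity-like values.

## Synthetic data

The generators define the conditions every test runs under.

* **Haplotype panels.** A target is (alt frequencies `p_A`, `p_B`,
  signed correlation `r`); the implied alt–alt haplotype frequency
  `p_11 = p_A·p_B + r·√(p_A q_A p_B q_B)` must lie within the Fréchet
  bounds or the spec is rejected with the admissible interval in the
  error. Panels are i.i.d. multinomial draws — no recombination maps,
  no coalescent realism, no LD decay with distance.
* **Loci.** Star topology: satellites are drawn conditionally on a
  single anchor, so satellite–satellite correlation arises only through
  the anchor (`r_XY = r_X·r_Y`). This is deliberately minimal: it is
  sufficient to exercise candidate-set intersection with planted truth,
  while a full LD matrix would be over-parameterised. Default panel
  sizes are 1008 EAS + 1006 EUR haplotypes (504 + 503 diploid samples),
  the size of a phase-3 1000-Genomes-style two-population panel; tests
  that check estimator tolerance use 20,000 haplotypes, where the
  binomial sampling bound on r̂² is about ±0.02. The reference FASTA can
  embed a GCATG context at the anchor with the motif-completing allele
  at a chosen motif base.
* **Clones.** Default design 5 risk-allele vs 5 non-risk clones. Each
  clone draws a skipped ratio around its group mean (non-risk mean 0.6;
  risk effect −0.3 by default, i.e. skipping decreased by the risk
  allele) with multiplicative lognormal noise (log-sd 0.15), and an
  overall isoform output drawn independently of genotype, partitioned
  so the measured ratio equals the drawn one. Total output being
  genotype-independent by construction means the total-expression null
  check holds in simulation — which is what the design intends to show;
  it does not test for expression effects real data might carry.
  Lognormal noise keeps abundances positive; no electropherogram-level
  error model is attempted.

What passing these tests shows: the estimators, the set algebra and the
tests behave correctly under idealised HWE panels and lognormal clone
noise. What it does not show: robustness to genotyping error,
population stratification within a panel, LD computed from array
subsets vs sequencing, or non-lognormal measurement error.

## Numerical and degenerate-input policy

Multiallelic and indel records are skipped on read (with a count), not
split. Unphased or missing calls make haplotype conversion fail loudly,
naming sample and variant. A monomorphic lead is an error (its profile
is meaningless); a monomorphic partner is an undefined entry. Zero
full-length abundance is an error naming the clone. Zero-length skips
are the identity. Reports order ties by (position, id).

## Problem sizes

The default verification suite simulates panels of 2×10⁴ haplotypes for
tolerance checks, 2,014 for end-to-end planted-truth runs, exhaustive
Mann–Whitney enumeration up to 8 per group, and 300–1000 replicate
null-calibration runs of the 5-vs-5 clone experiment — sizes chosen so
the planted effects are resolvable at the stated tolerances.

## Known limitations

* LD targets are expectations; realized r² carries binomial sampling
  error (the truth table records both).
* The star topology cannot represent haplotype blocks with multiple
  internal recombination breakpoints.
* The EM is strictly two-locus; no multi-locus haplotype estimation.
* Exact Mann–Whitney enumeration is combinatorial; beyond 20 pooled
  observations the normal approximation is used and `method` says so.
* Real-locus reproductions must supply their own window, panel and
  transcript annotation; printed amino-acid losses follow whatever exon
  coordinates the annotation provides.
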