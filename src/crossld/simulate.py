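"""Synthetic fixtures: LD-structured haplotype panels, loci, clone tables.

Three generators cover every input the pipeline consumes, so the whole
analysis is testable without downloads:

* :func:`simulate_haplotypes` — a two-variant panel drawn from the
  four-haplotype multinomial implied by target allele frequencies and a
  signed correlation r (so r² is controlled exactly in expectation).
* :func:`simulate_region` — a multi-variant locus with a star LD
  topology: every satellite variant is correlated with a single anchor
  (satellite–satellite LD arises only through the anchor), optionally
  per population, written out as phased VCF + reference FASTA + a truth
  table of target vs realized r². The FASTA can embed a splicing-motif
  context at the anchor so the motif scanner sees a created/destroyed
  instance by construction.
* :func:`simulate_clones` — knock-in clone abundance tables with a
  controllable genotype effect on the skipped-isoform ratio
  (default design: 5 risk-allele vs 5 non-risk clones), with
  multiplicative lognormal noise on positive abundances.

All generators take explicit seeds; the same seed yields byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    GenotypeMatrix,
    HaplotypeMatrix,
    SampleSet,
    VariantRecord,
    write_vcf,
)
from .motifs import MotifDef


def implied_joint(pA: float, pB: float, r_signed: float) -> float:
    """Alt–alt haplotype frequency implied by (pA, pB, r).

    Raises when the implied frequency leaves the Fréchet bounds
    [max(0, pA+pB−1), min(pA, pB)], i.e. the spec is infeasible.
    """
    qA, qB = 1 - pA, 1 - pB
    p11 = pA * pB + r_signed * math.sqrt(pA * qA * pB * qB)
    lo, hi = max(0.0, pA + pB - 1), min(pA, pB)
    if not lo - 1e-12 <= p11 <= hi + 1e-12:
        raise ValueError(
            f"infeasible LD target: implied alt-alt frequency {p11:.5f} "
            f"outside admissible [{lo:.5f}, {hi:.5f}] for "
            f"pA={pA}, pB={pB}, r={r_signed}"
        )
    return min(max(p11, lo), hi)


@dataclass(frozen=True)
class LDTargetSpec:
    """Target for a two-variant panel: alt frequencies, signed r, size."""

    pA: float
    pB: float
    r_signed: float
    n_haplotypes: int
    seed: int

    def __post_init__(self) -> None:
        for p in (self.pA, self.pB):
            if not 0 < p < 1:
                raise ValueError(f"allele frequency {p} outside (0, 1)")
        implied_joint(self.pA, self.pB, self.r_signed)  # feasibility
        if self.n_haplotypes < 2:
            raise ValueError("need at least 2 haplotypes")


def simulate_haplotypes(
    spec: LDTargetSpec,
    chrom: str = "chr2",
    positions: tuple[int, int] = (1000, 2000),
    ids: tuple[str, str] = ("anchor", "satellite"),
) -> HaplotypeMatrix:
    """Draw a two-variant haplotype panel from the implied multinomial."""
    p11 = implied_joint(spec.pA, spec.pB, spec.r_signed)
    p10 = spec.pA - p11  # alt at A, ref at B
    p01 = spec.pB - p11
    p00 = 1 - p11 - p10 - p01
    rng = np.random.default_rng(spec.seed)
    draws = rng.choice(
        4, size=spec.n_haplotypes, p=[p00, p01, p10, p11]
    )
    haps = np.column_stack([(draws >> 1) & 1, draws & 1]).astype(np.uint8)
    variants = [
        VariantRecord(chrom, positions[0], ids[0], "A", "G"),
        VariantRecord(chrom, positions[1], ids[1], "A", "G"),
    ]
    return HaplotypeMatrix(variants, haps, ["SIM"] * spec.n_haplotypes)


@dataclass(frozen=True)
class SatelliteSpec:
    """One satellite variant of a simulated locus."""

    id: str
    pos: int
    freq: float  # alt-allele frequency
    r_signed: float  # correlation with the anchor (default, all pops)
    ref: str = "A"
    alt: str = "G"
    r_by_population: tuple[tuple[str, float], ...] = ()

    def r_for(self, population: str) -> float:
        return dict(self.r_by_population).get(population, self.r_signed)


@dataclass(frozen=True)
class MotifEmbedding:
    """Embed a motif context at the anchor in the reference FASTA.

    ``variant_base`` is the 1-based position of the anchor within the
    motif; ``motif_allele`` is the allele that completes the pattern.
    """

    pattern: str = "GCATG"
    variant_base: int = 3
    motif_allele: str = "A"

    def __post_init__(self) -> None:
        if not 1 <= self.variant_base <= len(self.pattern):
            raise ValueError("variant_base outside motif")
        MotifDef(pattern=self.pattern)  # validates alphabet


@dataclass
class RegionSpec:
    """A simulated locus: anchor + satellites in a star LD topology."""

    chrom: str = "chr2"
    region_start: int = 1
    region_end: int = 20000
    anchor_id: str = "rs_anchor"
    anchor_pos: int = 10000
    anchor_freq: float = 0.5
    anchor_ref: str = "A"
    anchor_alt: str = "T"
    satellites: list[SatelliteSpec] = field(default_factory=list)
    n_haplotypes_by_population: dict[str, int] = field(
        default_factory=lambda: {"EAS": 1008, "EUR": 1006}
    )
    seed: int = 0
    motif: MotifEmbedding | None = None

    def __post_init__(self) -> None:
        positions = [s.pos for s in self.satellites] + [self.anchor_pos]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate variant positions")
        for s in self.satellites:
            if not self.region_start <= s.pos <= self.region_end:
                raise ValueError(f"satellite {s.id} outside region")
            implied_joint(self.anchor_freq, s.freq, s.r_signed)
            for _, r in s.r_by_population:
                implied_joint(self.anchor_freq, s.freq, r)
        for n in self.n_haplotypes_by_population.values():
            if n < 2 or n % 2:
                raise ValueError(
                    "per-population haplotype counts must be even and >= 2"
                )


def _draw_population(
    spec: RegionSpec, population: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n haplotypes over anchor + satellites for one population.

    Anchor alleles are Bernoulli(anchor_freq); each satellite is drawn
    conditional on the anchor allele so the joint matches the implied
    two-locus multinomial exactly, and satellites are conditionally
    independent given the anchor (star topology).
    """
    anchor = (rng.random(n) < spec.anchor_freq).astype(np.uint8)
    pA = spec.anchor_freq
    cols = [anchor]
    for sat in spec.satellites:
        p11 = implied_joint(pA, sat.freq, sat.r_for(population))
        p_given_alt = p11 / pA
        p_given_ref = (sat.freq - p11) / (1 - pA)
        u = rng.random(n)
        col = np.where(
            anchor == 1, u < p_given_alt, u < p_given_ref
        ).astype(np.uint8)
        cols.append(col)
    return np.column_stack(cols)


def _region_variants(spec: RegionSpec) -> tuple[list[VariantRecord], list[int]]:
    """Variant records in position order, plus draw-column order indices."""
    recs = [
        VariantRecord(
            spec.chrom, spec.anchor_pos, spec.anchor_id,
            spec.anchor_ref, spec.anchor_alt,
        )
    ] + [
        VariantRecord(spec.chrom, s.pos, s.id, s.ref, s.alt)
        for s in spec.satellites
    ]
    order = sorted(range(len(recs)), key=lambda i: recs[i].pos)
    return [recs[i] for i in order], order


def simulate_region_matrix(spec: RegionSpec) -> GenotypeMatrix:
    """Draw the locus as a phased GenotypeMatrix (samples paired per pop)."""
    rng = np.random.default_rng(spec.seed)
    records, order = _region_variants(spec)
    all_haps, sample_ids, pops = [], [], []
    for pop in sorted(spec.n_haplotypes_by_population):
        n = spec.n_haplotypes_by_population[pop]
        haps = _draw_population(spec, pop, n, rng)[:, order]
        all_haps.append(haps)
        for k in range(n // 2):
            sid = f"{pop}_{k:05d}"
            sample_ids.append(sid)
            pops.append(pop)
    haps = np.concatenate(all_haps, axis=0)
    n_samples = haps.shape[0] // 2
    calls = haps.reshape(n_samples, 2, len(records)).transpose(0, 2, 1)
    samples = SampleSet(sample_ids, dict(zip(sample_ids, pops)))
    phased = np.ones((n_samples, len(records)), dtype=bool)
    return GenotypeMatrix(records, samples, calls.astype(np.int8), phased)


def _reference_sequence(spec: RegionSpec, rng: np.random.Generator) -> str:
    length = spec.region_end - spec.region_start + 1
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length)
    if spec.motif is not None:
        m = spec.motif
        # place the pattern so its variant_base-th base sits on the anchor
        start = (spec.anchor_pos - spec.region_start) - (m.variant_base - 1)
        if start < 0 or start + len(m.pattern) > length:
            raise ValueError("motif context does not fit inside the region")
        word = list(m.pattern.upper())
        word[m.variant_base - 1] = m.motif_allele.upper()
        seq[start : start + len(m.pattern)] = list("".join(word))
        # the motif-completing base must equal one of the anchor alleles;
        # the reference FASTA carries the anchor's ref allele
        seq[spec.anchor_pos - spec.region_start] = spec.anchor_ref
    else:
        seq[spec.anchor_pos - spec.region_start] = spec.anchor_ref
    for s in spec.satellites:
        seq[s.pos - spec.region_start] = s.ref
    return "".join(seq)


def simulate_region(
    spec: RegionSpec, out_dir: str | Path
) -> dict[str, Path]:
    """Write the simulated locus as VCF + FASTA + truth table.

    Returns paths to ``region.vcf`` (phased genotypes),
    ``reference.fa``, ``samples.tsv`` (sample→population map) and
    ``truth.tsv`` (per satellite: target and realized pooled r²).
    Deterministic per seed.
    """
    from . import ld

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = simulate_region_matrix(spec)
    vcf_path = out / "region.vcf"
    write_vcf(g, str(vcf_path))

    fa_path = out / "reference.fa"
    rng = np.random.default_rng(spec.seed + 1)
    seq = _reference_sequence(spec, rng)
    with open(fa_path, "w") as fh:
        fh.write(f">{spec.chrom}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")

    map_path = out / "samples.tsv"
    pd.DataFrame(
        {
            "sample": g.samples.sample_ids,
            "population": [
                g.samples.population[s] for s in g.samples.sample_ids
            ],
        }
    ).to_csv(map_path, sep="\t", index=False)

    from .genotype_io import to_haplotypes

    h = to_haplotypes(g)
    rows = []
    for sat in spec.satellites:
        f = ld.hap_freqs_phased(h, spec.anchor_id, sat.id)
        stats = ld.ld_stats(f)
        rows.append(
            {
                "variant_id": sat.id,
                "pos": sat.pos,
                "target_r2": sat.r_signed**2,
                "realized_r2": stats.r2,
            }
        )
    truth_path = out / "truth.tsv"
    pd.DataFrame(rows).to_csv(truth_path, sep="\t", index=False)
    return {
        "vcf": vcf_path,
        "fasta": fa_path,
        "sample_map": map_path,
        "truth": truth_path,
    }


@dataclass(frozen=True)
class CloneSimSpec:
    """Design of a simulated knock-in clone experiment.

    ``baseline_ratio`` is the mean skipped-isoform ratio in the non-risk
    genotype group; ``effect`` is the additive shift in the risk group
    (negative = skipping decreased by the risk allele, the observed
    direction); noise is multiplicative lognormal with scale
    ``noise_sd`` on the log.
    """

    n_per_genotype: int = 5
    baseline_ratio: float = 0.6
    effect: float = -0.3
    noise_sd: float = 0.15
    risk_genotype: str = "AA"
    nonrisk_genotype: str = "TT"
    base_total_abundance: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_genotype < 2:
            raise ValueError("need at least 2 clones per genotype group")
        if self.baseline_ratio <= 0:
            raise ValueError("baseline_ratio must be positive")
        if self.baseline_ratio + self.effect <= 0:
            raise ValueError(
                "baseline_ratio + effect must stay positive (abundances "
                "cannot be negative)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_clones(spec: CloneSimSpec) -> pd.DataFrame:
    """Simulate an isoform abundance table for knock-in clones.

    Per clone, a target skipped ratio is drawn around its group mean
    with multiplicative lognormal noise, and the clone's *total* isoform
    output is drawn independently of genotype (lognormal around
    ``base_total_abundance``) — the genotype shifts splicing
    composition, not overall output, so the total-expression null check
    holds by construction. Abundances are partitioned so that the
    measured ratio (partial + full skip) / full equals the drawn ratio
    exactly; the partial-skip isoform takes 60% of the skipped molarity,
    the full-skip isoform 40%.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    groups = [
        (spec.risk_genotype, spec.baseline_ratio + spec.effect),
        (spec.nonrisk_genotype, spec.baseline_ratio),
    ]
    clone_no = 0
    for genotype, mean_ratio in groups:
        for _ in range(spec.n_per_genotype):
            clone_no += 1
            ratio = mean_ratio * math.exp(
                rng.normal(0.0, spec.noise_sd)
            )
            total = spec.base_total_abundance * math.exp(
                rng.normal(0.0, spec.noise_sd)
            )
            full = total / (1.0 + ratio)
            skipped = total - full
            rows.append(
                {
                    "clone_id": f"clone_{clone_no:02d}",
                    "genotype": genotype,
                    "full": full,
                    "cd28i": 0.6 * skipped,
                    "dex2": 0.4 * skipped,
                }
            )
    return pd.DataFrame(rows)
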