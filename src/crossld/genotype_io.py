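"""Genotype, sequence and tabular input handling.

Reads VCF genotypes into the package's internal matrix types, converts
phased diploid calls to haplotypes, pools population panels, and extracts
reference-sequence context windows.

Coordinate conventions: all external I/O (VCF, FASTA requests, region
strings) is 1-based inclusive; internal array arithmetic is 0-based.
Only the GT field of a VCF is consulted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from pyfaidx import Fasta

log = logging.getLogger(__name__)

_DNA = frozenset("ACGT")

MISSING = -1  # allele-index sentinel for missing calls


class VcfFormatError(ValueError):
    """Raised when a VCF record cannot be parsed into the data model."""


@dataclass(frozen=True, order=True)
class VariantRecord:
    """A biallelic SNV.

    pos is the 1-based genomic position; ref and alt are single bases.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.id}: ref equals alt ({self.ref})")
        for allele in (self.ref, self.alt):
            if len(allele) != 1 or allele not in _DNA:
                raise ValueError(
                    f"{self.id}: alleles must be single bases in ACGT, "
                    f"got ref={self.ref!r} alt={self.alt!r}"
                )
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1")


@dataclass
class SampleSet:
    """Ordered sample identifiers with a population code per sample."""

    sample_ids: list[str]
    population: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.population]
        if missing:
            raise ValueError(f"samples without population code: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass
class GenotypeMatrix:
    """Diploid calls for biallelic SNVs in one region.

    calls has shape (n_samples, n_variants, 2) with allele indices 0/1 and
    -1 for missing; phased has shape (n_samples, n_variants).
    """

    variants: list[VariantRecord]
    samples: SampleSet
    calls: np.ndarray
    phased: np.ndarray
    n_skipped: int = 0  # multiallelic / non-SNV records dropped on read

    def __post_init__(self) -> None:
        ns, nv = len(self.samples), len(self.variants)
        if self.calls.shape != (ns, nv, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({ns}, {nv}, 2)"
            )
        if self.phased.shape != (ns, nv):
            raise ValueError("phased shape inconsistent with calls")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == variant_id:
                return i
        raise KeyError(f"variant {variant_id!r} not in matrix")


@dataclass
class HaplotypeMatrix:
    """Binary haplotypes (0 = ref, 1 = alt), one population code each."""

    variants: list[VariantRecord]
    haplotypes: np.ndarray  # (n_haplotypes, n_variants), entries in {0,1}
    source_populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != len(self.variants):
            raise ValueError("haplotype width != number of variants")
        if self.haplotypes.size and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")
        if self.source_populations and len(self.source_populations) != len(
            self.haplotypes
        ):
            raise ValueError("one population code per haplotype required")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def variant_index(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == variant_id:
                return i
        raise KeyError(f"variant {variant_id!r} not in matrix")


_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive)."""
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region {region!r}, expected chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start > end:
        raise ValueError(f"region start {start} > end {end}")
    return chrom, start, end


def read_sample_map(path: str) -> SampleSet:
    """Read a TSV with header ``sample<TAB>population``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "population"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'sample' and 'population'")
    return SampleSet(
        sample_ids=df["sample"].tolist(),
        population=dict(zip(df["sample"], df["population"])),
    )


def read_vcf(
    path: str,
    region: str | None = None,
    samples: SampleSet | None = None,
) -> GenotypeMatrix:
    """Read biallelic SNVs from a VCF into a GenotypeMatrix.

    Multiallelic records and indels are skipped; the count of skipped
    records is logged and stored on the returned matrix. Variants are
    returned in position order. A region restricts to records whose POS
    lies inside ``chrom:start-end`` (1-based inclusive).
    """
    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    if samples is not None:
        unknown = [s for s in samples.sample_ids if s not in vcf_samples]
        if unknown:
            raise KeyError(f"samples not in VCF: {unknown[:5]}")
        keep = samples.sample_ids
    else:
        keep = vcf_samples
        samples = SampleSet(keep, {s: "NA" for s in keep})
    col = {s: vcf_samples.index(s) for s in keep}

    want = parse_region(region) if region is not None else None

    kept_records: list[VariantRecord] = []
    kept_calls: list[np.ndarray] = []
    kept_phased: list[np.ndarray] = []
    n_skipped = 0
    for rec_no, v in enumerate(vcf, start=1):
        try:
            if want is not None:
                chrom, start, end = want
                if v.CHROM != chrom or not (start <= v.POS <= end):
                    continue
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                n_skipped += 1
                continue
            if v.REF not in _DNA or v.ALT[0] not in _DNA:
                n_skipped += 1
                continue
            gts = v.genotypes  # per sample: [a0, a1, phased]
            calls = np.full((len(keep), 2), MISSING, dtype=np.int8)
            phased = np.zeros(len(keep), dtype=bool)
            for i, s in enumerate(keep):
                g = gts[col[s]]
                a0, a1 = g[0], g[1]
                calls[i, 0] = a0 if a0 >= 0 else MISSING
                calls[i, 1] = a1 if a1 >= 0 else MISSING
                phased[i] = bool(g[-1])
            vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
            kept_records.append(
                VariantRecord(v.CHROM, v.POS, vid, v.REF, v.ALT[0])
            )
            kept_calls.append(calls)
            kept_phased.append(phased)
        except VcfFormatError:
            raise
        except Exception as exc:  # cyvcf2 gives no line numbers
            raise VcfFormatError(
                f"{path}: malformed VCF data record #{rec_no}: {exc}"
            ) from exc

    if n_skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNV records", n_skipped)

    order = np.argsort([r.pos for r in kept_records], kind="stable")
    variants = [kept_records[i] for i in order]
    if kept_calls:
        calls = np.stack([kept_calls[i] for i in order], axis=1)
        phased = np.stack([kept_phased[i] for i in order], axis=1)
    else:
        calls = np.empty((len(keep), 0, 2), dtype=np.int8)
        phased = np.empty((len(keep), 0), dtype=bool)
    return GenotypeMatrix(variants, samples, calls, phased, n_skipped=n_skipped)


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as a minimal VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = sorted({v.chrom for v in g.variants})
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples.sample_ids)
            + "\n"
        )
        for j, v in enumerate(g.variants):
            cells = []
            for i in range(len(g.samples)):
                a0, a1 = g.calls[i, j]
                sep = "|" if g.phased[i, j] else "/"
                s0 = "." if a0 == MISSING else str(int(a0))
                s1 = "." if a1 == MISSING else str(int(a1))
                cells.append(f"{s0}{sep}{s1}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(cells)
                + "\n"
            )


def to_haplotypes(g: GenotypeMatrix) -> HaplotypeMatrix:
    """Split phased diploid calls into 2N haplotypes.

    Every call must be phased and non-missing; allele order follows the
    GT phase. Population labels are copied to both haplotypes of a sample.
    """
    for i, s in enumerate(g.samples.sample_ids):
        for j, v in enumerate(g.variants):
            if g.n_variants and not g.phased[i, j]:
                raise ValueError(
                    f"unphased call for sample {s!r} at variant {v.id!r}"
                )
            if MISSING in g.calls[i, j]:
                raise ValueError(
                    f"missing call for sample {s!r} at variant {v.id!r}"
                )
    n = len(g.samples)
    haps = g.calls.transpose(0, 2, 1).reshape(2 * n, g.n_variants)
    pops = []
    for s in g.samples.sample_ids:
        pops.extend([g.samples.population[s]] * 2)
    return HaplotypeMatrix(list(g.variants), haps.astype(np.uint8), pops)


def pool_populations(matrices: list[HaplotypeMatrix]) -> HaplotypeMatrix:
    """Concatenate haplotype panels sharing one variant list.

    This is how a multi-population ("combined") LD panel is formed:
    haplotypes are pooled into one panel before any counting, keeping
    their population labels.
    """
    if not matrices:
        raise ValueError("no matrices to pool")
    ref = matrices[0]
    for m in matrices[1:]:
        if len(m.variants) != len(ref.variants):
            raise ValueError("variant list length mismatch between panels")
        for a, b in zip(ref.variants, m.variants):
            if a != b:
                raise ValueError(
                    f"variant mismatch between panels at {a.id!r} vs {b.id!r}"
                )
    haps = np.concatenate([m.haplotypes for m in matrices], axis=0)
    pops: list[str] = []
    for m in matrices:
        pops.extend(
            m.source_populations or ["NA"] * m.n_haplotypes
        )
    return HaplotypeMatrix(list(ref.variants), haps, pops)


def read_fasta_context(path: str, chrom: str, start: int, end: int) -> str:
    """Return the uppercase sequence of chrom:start-end (1-based inclusive)."""
    if start < 1 or start > end:
        raise ValueError(f"bad coordinates {start}-{end}")
    fa = Fasta(str(path))
    if chrom not in fa:
        raise KeyError(f"contig {chrom!r} not in {path}")
    if end > len(fa[chrom]):
        raise ValueError(
            f"{chrom}:{start}-{end} outside contig of length {len(fa[chrom])}"
        )
    return str(fa[chrom][start - 1 : end]).upper()
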