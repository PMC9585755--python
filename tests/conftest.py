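import textwrap

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True)
settings.load_profile("derandomized")

from crossld.genotype_io import (
    GenotypeMatrix,
    HaplotypeMatrix,
    SampleSet,
    VariantRecord,
)

TOY_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##contig=<ID=chr2>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
    chr2\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1
    chr2\t200\trs_indel\tAT\tA\t.\tPASS\t.\tGT\t0|0\t0|1
    chr2\t300\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0\t0|1
    """
)

TOY_VCF_MULTIALLELIC = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##contig=<ID=chr2>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
    chr2\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1
    chr2\t150\trs_multi\tA\tG,T\t.\tPASS\t.\tGT\t1|2
    chr2\t300\trs2\tC\tT\t.\tPASS\t.\tGT\t0|0
    """
)


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def toy_vcf_multiallelic(tmp_path):
    p = tmp_path / "multi.vcf"
    p.write_text(TOY_VCF_MULTIALLELIC)
    return p


@pytest.fixture
def toy_fasta(tmp_path):
    p = tmp_path / "toy.fa"
    p.write_text(">chrT\nacgtACGTac\nGGGGGCATGG\n")
    return p


def make_haplotypes(columns: dict[str, list[int]], populations=None):
    """Build a HaplotypeMatrix from per-variant allele columns."""
    ids = list(columns)
    n = len(next(iter(columns.values())))
    variants = [
        VariantRecord("chr2", 100 * (i + 1), vid, "A", "G")
        for i, vid in enumerate(ids)
    ]
    haps = np.array([columns[vid] for vid in ids], dtype=np.uint8).T
    pops = populations or ["POP"] * n
    return HaplotypeMatrix(variants, haps, pops)


def make_genotypes(columns: dict[str, list[tuple[int, int]]], phased=True):
    """Build a GenotypeMatrix from per-variant lists of diploid calls."""
    ids = list(columns)
    n = len(next(iter(columns.values())))
    variants = [
        VariantRecord("chr2", 100 * (i + 1), vid, "A", "G")
        for i, vid in enumerate(ids)
    ]
    sample_ids = [f"s{i}" for i in range(n)]
    samples = SampleSet(sample_ids, {s: "POP" for s in sample_ids})
    calls = np.zeros((n, len(ids), 2), dtype=np.int8)
    for j, vid in enumerate(ids):
        for i, (a0, a1) in enumerate(columns[vid]):
            calls[i, j] = (a0, a1)
    ph = np.full((n, len(ids)), bool(phased))
    return GenotypeMatrix(variants, samples, calls, ph)


def genotype_table_to_matrix(table):
    """3x3 array of genotype-pair counts -> unphased GenotypeMatrix."""
    gcalls = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    colA, colB = [], []
    for ga in range(3):
        for gb in range(3):
            for _ in range(int(table[ga][gb])):
                colA.append(gcalls[ga])
                colB.append(gcalls[gb])
    return make_genotypes({"vA": colA, "vB": colB}, phased=False)
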