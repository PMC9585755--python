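"""Exon-skipping isoform analysis and genotype association testing.

Two halves:

* **Quantitative** — per-clone skipped-isoform ratios from a molarity
  table (full-length, partial-skip and full-skip isoform abundances) and
  an exact two-sided Mann–Whitney U test between genotype groups. With
  n = 5 vs 5 clones the exact null distribution of U has only
  C(10,5) = 252 assignments, so complete enumeration is the correct
  test; the normal approximation (with tie correction) is used only for
  larger samples.

* **Structural** — transcript models with exon intervals and a CDS,
  skip events removing all or part of an exon, and translation of the
  resulting open reading frame to measure the protein consequence:
  how many amino acids are deleted when the reading frame is preserved,
  or whether a premature termination codon (PTC) appears when it is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

EXACT_MAX_N = 20  # complete enumeration up to nA + nB = 20

ABUNDANCE_COLUMNS = ["clone_id", "genotype", "full", "cd28i", "dex2"]


# ---------------------------------------------------------------------------
# abundance tables and ratios


def validate_abundance_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check an isoform abundance table and return it unchanged.

    Columns: clone_id, genotype, full, cd28i, dex2 (molarity-like,
    non-negative). Clone ids must be unique.
    """
    missing = [c for c in ABUNDANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"abundance table missing columns {missing}")
    if df["clone_id"].duplicated().any():
        dupes = df.loc[df["clone_id"].duplicated(), "clone_id"].tolist()
        raise ValueError(f"duplicate clone ids {dupes}")
    for col in ("full", "cd28i", "dex2"):
        if (df[col] < 0).any():
            raise ValueError(f"negative abundance in column {col!r}")
    return df


def read_abundance_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_abundance_table(df)


def skipped_ratio(table: pd.DataFrame) -> pd.Series:
    """Per-clone skipped-isoform ratio, (partial + full skip) / full-length.

    The full-length isoform is the denominator. An alternative
    skipped/(skipped+full) fraction is available via
    :func:`skipped_fraction`.
    """
    validate_abundance_table(table)
    zero = table.loc[table["full"] == 0, "clone_id"].tolist()
    if zero:
        raise ValueError(
            f"abundance_full is zero for clone(s) {zero}; ratio undefined"
        )
    ratio = (table["cd28i"] + table["dex2"]) / table["full"]
    ratio.index = table["clone_id"]
    return ratio.rename("skipped_ratio")


def skipped_fraction(table: pd.DataFrame) -> pd.Series:
    """Secondary measure: skipped / (skipped + full-length)."""
    validate_abundance_table(table)
    skipped = table["cd28i"] + table["dex2"]
    total = skipped + table["full"]
    if (total == 0).any():
        raise ValueError("total abundance is zero for some clone")
    frac = skipped / total
    frac.index = table["clone_id"]
    return frac.rename("skipped_fraction")


# ---------------------------------------------------------------------------
# exact Mann–Whitney U


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    nA: int
    nB: int


def _u_statistic(ranks_a: np.ndarray, nA: int) -> float:
    return float(ranks_a.sum() - nA * (nA + 1) / 2)


def mannwhitney_exact(
    group_a, group_b
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test, exact by complete enumeration.

    Midranks handle ties. For nA + nB <= 20 the p-value is exact:
    the probability, over all C(nA+nB, nA) equally likely assignments of
    the pooled observations to groups, that |U − nA·nB/2| is at least the
    observed deviation. Larger samples use the normal approximation with
    the usual tie-corrected variance and a continuity correction of 1/2.
    U is reported for group A.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    nA, nB = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u_obs = _u_statistic(ranks[:nA], nA)
    mid = nA * nB / 2
    dev = abs(u_obs - mid)

    if nA + nB <= EXACT_MAX_N:
        n = nA + nB
        hits = total = 0
        for idx in combinations(range(n), nA):
            u = _u_statistic(ranks[list(idx)], nA)
            total += 1
            if abs(u - mid) >= dev - 1e-12:
                hits += 1
        p = hits / total
        return MannWhitneyResult(u_obs, min(p, 1.0), "exact", nA, nB)

    # tie-corrected normal approximation with continuity correction
    n = nA + nB
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    sigma2 = nA * nB / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return MannWhitneyResult(u_obs, 1.0, "normal_approx", nA, nB)
    z = max(dev - 0.5, 0.0) / math.sqrt(sigma2)
    p = min(1.0, 2 * stats.norm.sf(z))
    return MannWhitneyResult(u_obs, p, "normal_approx", nA, nB)


@dataclass(frozen=True)
class RatioComparison:
    """Genotype-stratified comparison of per-clone skipped ratios."""

    per_clone_ratio: pd.Series
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p_two_sided: float
    method: str


def compare_ratio_by_genotype(
    table: pd.DataFrame,
    group_a: str = "AA",
    group_b: str = "TT",
) -> RatioComparison:
    """Exact Mann–Whitney test of skipped ratios between two genotypes."""
    ratios = skipped_ratio(table)
    geno = table.set_index("clone_id")["genotype"]
    ra = ratios[geno == group_a]
    rb = ratios[geno == group_b]
    if ra.empty or rb.empty:
        raise ValueError(
            f"need clones of both genotypes {group_a!r} and {group_b!r}"
        )
    res = mannwhitney_exact(ra.to_numpy(), rb.to_numpy())
    return RatioComparison(
        ratios, group_a, group_b, res.nA, res.nB,
        res.U, res.p_two_sided, res.method,
    )


def total_expression_test(
    table: pd.DataFrame,
    group_a: str = "AA",
    group_b: str = "TT",
) -> MannWhitneyResult:
    """Null check: is *total* isoform output associated with genotype?

    Applies the same exact test to (full + partial-skip + full-skip)
    totals per clone. A splicing-shift variant moves the ratio, not the
    total.
    """
    validate_abundance_table(table)
    totals = table["full"] + table["cd28i"] + table["dex2"]
    geno = table["genotype"]
    ta = totals[geno == group_a]
    tb = totals[geno == group_b]
    if ta.empty or tb.empty:
        raise ValueError(
            f"need clones of both genotypes {group_a!r} and {group_b!r}"
        )
    return mannwhitney_exact(ta.to_numpy(), tb.to_numpy())


# ---------------------------------------------------------------------------
# transcript models, skip events, translation


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure plus transcript-relative CDS coordinates.

    Exons are genomic intervals (0-based half-open), non-overlapping and
    ordered 5'→3' along the transcript; for minus-strand models they are
    therefore in decreasing genomic order. cds_start/cds_end are 0-based
    half-open offsets into the spliced transcript.
    """

    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty/inverted exon ({s}, {e})")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError("overlapping exons")
        expected = (
            tuple(genomic) if self.strand == "+" else tuple(genomic[::-1])
        )
        if tuple(self.exons) != expected:
            raise ValueError("exons must be ordered 5'->3' along the strand")
        if not 0 <= self.cds_start < self.cds_end <= self.transcript_length:
            raise ValueError("CDS outside transcript bounds")

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    def spliced_sequence(self, genome) -> str:
        """Spliced transcript sequence; ``genome`` maps chrom -> sequence."""
        contig = genome[self.chrom]
        parts = []
        for s, e in self.exons:
            piece = str(contig[s:e]).upper()
            if self.strand == "-":
                piece = str(Seq(piece).reverse_complement())
            parts.append(piece)
        return "".join(parts)


@dataclass(frozen=True)
class SkipEvent:
    """A splicing event removing all or part of one exon.

    ``kind`` is "full_exon" or "partial_exon"; for partial events,
    ``region`` is the skipped genomic sub-interval (0-based half-open)
    which must lie inside the target exon.
    """

    kind: str
    exon_index: int
    region: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("full_exon", "partial_exon"):
            raise ValueError(f"unknown skip kind {self.kind!r}")
        if self.kind == "partial_exon" and self.region is None:
            raise ValueError("partial_exon skip requires a region")


@dataclass(frozen=True)
class IsoformProtein:
    """Protein-level consequence of a skip relative to full-length."""

    length_aa: int
    full_length_aa: int
    frame_preserved: bool
    aa_deleted: int | None  # full − isoform length, when frame preserved
    ptc_introduced: bool
    sequence: str


def _transcript_offset(m: TranscriptModel, genomic_pos: int) -> int:
    """Transcript-relative offset of a genomic position inside an exon."""
    acc = 0
    for s, e in m.exons:
        if s <= genomic_pos < e:
            if m.strand == "+":
                return acc + (genomic_pos - s)
            return acc + (e - 1 - genomic_pos)
        acc += e - s
    raise ValueError(f"position {genomic_pos} not exonic")


def apply_skip(m: TranscriptModel, event: SkipEvent) -> TranscriptModel:
    """Return a new model with the skipped region removed.

    Transcript-relative CDS coordinates are re-derived: removed bases
    upstream of the CDS shift both ends; removed coding bases shorten
    cds_end (a bookkeeping of the surviving originally-coding bases —
    under a frameshift the true stop is found later by translation).
    The input model is untouched.
    """
    if not 0 <= event.exon_index < len(m.exons):
        raise ValueError(f"exon index {event.exon_index} out of range")
    s, e = m.exons[event.exon_index]
    if event.kind == "full_exon":
        rs, re_ = s, e
    else:
        rs, re_ = event.region  # type: ignore[misc]
        if not (s <= rs and re_ <= e):
            raise ValueError(
                f"skip region ({rs}, {re_}) not inside exon ({s}, {e})"
            )
        if rs > re_:
            raise ValueError("inverted skip region")
        if rs == re_:
            return m  # zero-length skip: identity

    # transcript-relative half-open interval removed
    if m.strand == "+":
        t_lo = _transcript_offset(m, rs)
    else:
        t_lo = _transcript_offset(m, re_ - 1)
    t_hi = t_lo + (re_ - rs)

    removed_before_cds = max(0, min(t_hi, m.cds_start) - t_lo)
    removed_coding = max(
        0, min(t_hi, m.cds_end) - max(t_lo, m.cds_start)
    )

    new_exons: list[tuple[int, int]] = []
    for i, (xs, xe) in enumerate(m.exons):
        if i != event.exon_index:
            new_exons.append((xs, xe))
            continue
        left = (xs, rs) if rs > xs else None
        right = (re_, xe) if re_ < xe else None
        pieces = [p for p in (left, right) if p is not None]
        if m.strand == "-":
            pieces = pieces[::-1]
        new_exons.extend(pieces)

    return TranscriptModel(
        name=f"{m.name}.skip",
        chrom=m.chrom,
        strand=m.strand,
        exons=tuple(new_exons),
        cds_start=m.cds_start - removed_before_cds,
        cds_end=m.cds_end - removed_before_cds - removed_coding,
    )


def translate_isoform(
    m: TranscriptModel, full: TranscriptModel, genome
) -> IsoformProtein:
    """Translate a skip isoform and measure its protein consequence.

    The full-length model's CDS must start with ATG. The isoform is
    translated from its (re-derived) CDS start to the first in-frame
    stop, scanning into downstream sequence when a frameshift pushes the
    stop beyond the original coding span. ``frame_preserved`` holds when
    the number of removed coding nucleotides is a multiple of three;
    ``ptc_introduced`` flags a stop upstream of where the full-length
    stop would fall.
    """
    full_tx = full.spliced_sequence(genome)
    full_cds = full_tx[full.cds_start : full.cds_end]
    if full_cds[:3] != "ATG":
        raise ValueError(
            f"full-length CDS starts with {full_cds[:3]!r}, not ATG"
        )
    full_prot = str(Seq(full_cds).translate(to_stop=True))

    removed_coding = full.cds_length - m.cds_length
    if removed_coding < 0:
        raise ValueError("isoform CDS longer than full-length CDS")
    frame_preserved = removed_coding % 3 == 0

    iso_tx = m.spliced_sequence(genome)
    scan = iso_tx[m.cds_start :]
    scan = scan[: len(scan) - len(scan) % 3]
    iso_prot = str(Seq(scan).translate(to_stop=True))

    # the homologous full-length stop maps to the last codon of the
    # surviving coding span; any earlier stop is premature
    stop_found = len(iso_prot) * 3 < len(scan)
    ptc = stop_found and len(iso_prot) * 3 < m.cds_length - 3
    aa_deleted = len(full_prot) - len(iso_prot) if frame_preserved else None
    return IsoformProtein(
        length_aa=len(iso_prot),
        full_length_aa=len(full_prot),
        frame_preserved=frame_preserved,
        aa_deleted=aa_deleted,
        ptc_introduced=bool(ptc),
        sequence=iso_prot,
    )


def read_transcript_model(path: str) -> TranscriptModel:
    """Read a transcript model TSV.

    Header lines ``#name``, ``#chrom``, ``#strand``, ``#cds_start``,
    ``#cds_end`` (transcript-relative), then one ``start<TAB>end`` exon
    line per exon in 5'→3' order (0-based half-open genomic).
    """
    meta: dict[str, str] = {}
    exons: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key.strip()] = value.strip()
            else:
                s, e = line.split("\t")[:2]
                exons.append((int(s), int(e)))
    return TranscriptModel(
        name=meta.get("name", "tx"),
        chrom=meta["chrom"],
        strand=meta.get("strand", "+"),
        exons=tuple(exons),
        cds_start=int(meta["cds_start"]),
        cds_end=int(meta["cds_end"]),
    )
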