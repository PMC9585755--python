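"""Two-locus linkage disequilibrium: haplotype frequencies, D, D', r².

Haplotype frequencies come either from direct counting of phased
haplotypes or from EM estimation on unphased diploid genotypes (the
classic two-locus EM in which only double heterozygotes carry phase
ambiguity). Conventions: locus labels A/a are the ref/alt alleles at the
first locus and B/b at the second, so pAB is the frequency of the
ref–ref haplotype and

    D   = pAB − pA·pB
    D'  = |D| / Dmax,  Dmax = min(pA·pb, pa·pB) if D > 0
                              else min(pA·pB, pa·pb)
    r²  = D² / (pA·pa·pB·pb)

LD is undefined (``defined=False``) when either locus is monomorphic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    HaplotypeMatrix,
    VariantRecord,
    to_haplotypes,
)

EM_TOL = 1e-8
EM_MAX_ITER = 1000


class EMConvergenceError(RuntimeError):
    """EM failed to converge; carries the last estimate."""

    def __init__(self, msg: str, last_estimate: "HaplotypeFreqs"):
        super().__init__(msg)
        self.last_estimate = last_estimate


@dataclass(frozen=True)
class HaplotypeFreqs:
    """Frequencies of the four two-locus haplotypes (A/B = ref alleles)."""

    pAB: float
    pAb: float
    paB: float
    pab: float
    n_used: int
    method: str  # "phased" | "em"

    def __post_init__(self) -> None:
        total = self.pAB + self.pAb + self.paB + self.pab
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        for p in (self.pAB, self.pAb, self.paB, self.pab):
            if not -1e-12 <= p <= 1 + 1e-12:
                raise ValueError(f"frequency {p} outside [0, 1]")

    @property
    def pA(self) -> float:
        return self.pAB + self.pAb

    @property
    def pB(self) -> float:
        return self.pAB + self.paB


@dataclass(frozen=True)
class LDStats:
    """D, D' and r² for one variant pair; NaN-valued when undefined."""

    D: float
    Dprime: float
    r2: float
    defined: bool


@dataclass
class LDProfile:
    """r²/D' of every variant in a region against one lead variant."""

    lead: VariantRecord
    entries: dict[str, tuple[int, LDStats]]  # id -> (pos, stats)
    n_used: dict[str, int] | None = None
    method: dict[str, str] | None = None


def hap_freqs_phased(
    h: HaplotypeMatrix, vA: str, vB: str
) -> HaplotypeFreqs:
    """Direct haplotype counting between two variants of a phased panel."""
    ia, ib = h.variant_index(vA), h.variant_index(vB)
    a = h.haplotypes[:, ia]
    b = h.haplotypes[:, ib]
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    # 0 = ref: AB is the (0, 0) haplotype
    nAB = int(np.sum((a == 0) & (b == 0)))
    nAb = int(np.sum((a == 0) & (b == 1)))
    naB = int(np.sum((a == 1) & (b == 0)))
    nab = int(np.sum((a == 1) & (b == 1)))
    return HaplotypeFreqs(nAB / n, nAb / n, naB / n, nab / n, n, "phased")


def _genotype_pair_counts(
    g: GenotypeMatrix, vA: str, vB: str
) -> np.ndarray:
    """3x3 table of complete-case genotype pairs (alt-allele counts 0/1/2)."""
    ia, ib = g.variant_index(vA), g.variant_index(vB)
    ca = g.calls[:, ia, :]
    cb = g.calls[:, ib, :]
    ok = (ca != MISSING).all(axis=1) & (cb != MISSING).all(axis=1)
    ga = ca[ok].sum(axis=1)
    gb = cb[ok].sum(axis=1)
    table = np.zeros((3, 3), dtype=np.int64)
    for x, y in zip(ga, gb):
        table[x, y] += 1
    return table


def hap_freqs_em(
    g: GenotypeMatrix,
    vA: str,
    vB: str,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HaplotypeFreqs:
    """EM estimate of two-locus haplotype frequencies from unphased calls.

    Individuals with a missing call at either locus are dropped
    (pairwise complete case). Initialization is at linkage equilibrium
    (pAB = pA·pB from genotype marginals), which makes the estimate
    deterministic and resolves the symmetric-maximum ambiguity of the
    all-double-heterozygote input in favour of equilibrium. The
    log-likelihood is non-decreasing across iterations; convergence is
    declared when the largest absolute frequency change drops below
    ``tol``.
    """
    table = _genotype_pair_counts(g, vA, vB)
    n = int(table.sum())
    if n < 2:
        raise ValueError("need >= 2 individuals with complete genotypes")

    # genotype marginals -> LE initialization
    ga = table.sum(axis=1)
    gb = table.sum(axis=0)
    fA = (2 * ga[0] + ga[1]) / (2 * n)  # ref-allele freq at locus 1
    fB = (2 * gb[0] + gb[1]) / (2 * n)
    p = np.array(
        [fA * fB, fA * (1 - fB), (1 - fA) * fB, (1 - fA) * (1 - fB)],
        dtype=float,
    )  # order: AB, Ab, aB, ab

    n_dh = table[1, 1]  # double heterozygotes: the only ambiguous class
    # fixed haplotype contributions from unambiguous genotype classes
    fixed = np.zeros(4, dtype=float)
    # genotype (i alt copies at A, j alt copies at B); haplotypes in terms
    # of ref alleles: index 0=AB, 1=Ab, 2=aB, 3=ab
    contrib = {
        (0, 0): (2, 0, 0, 0),
        (0, 1): (1, 1, 0, 0),
        (0, 2): (0, 2, 0, 0),
        (1, 0): (1, 0, 1, 0),
        (1, 2): (0, 1, 0, 1),
        (2, 0): (0, 0, 2, 0),
        (2, 1): (0, 0, 1, 1),
        (2, 2): (0, 0, 0, 2),
    }
    for (i, j), c in contrib.items():
        fixed += table[i, j] * np.asarray(c, dtype=float)

    for _ in range(max_iter):
        # E-step: split double heterozygotes between the two phasings
        # AaBb is either AB/ab (prob ∝ pAB·pab) or Ab/aB (∝ pAb·paB)
        w1 = p[0] * p[3]
        w2 = p[1] * p[2]
        tot = w1 + w2
        frac = 0.5 if tot == 0 else w1 / tot
        counts = fixed.copy()
        counts[0] += n_dh * frac
        counts[3] += n_dh * frac
        counts[1] += n_dh * (1 - frac)
        counts[2] += n_dh * (1 - frac)
        new_p = counts / (2 * n)
        delta = float(np.abs(new_p - p).max())
        p = new_p
        if delta < tol:
            return HaplotypeFreqs(p[0], p[1], p[2], p[3], n, "em")
    raise EMConvergenceError(
        f"EM did not converge in {max_iter} iterations",
        HaplotypeFreqs(p[0], p[1], p[2], p[3], n, "em"),
    )


def ld_stats(f: HaplotypeFreqs) -> LDStats:
    """Compute D, D' and r² from two-locus haplotype frequencies."""
    pA, pB = f.pA, f.pB
    pa, pb = 1 - pA, 1 - pB
    if min(pA, pa, pB, pb) <= 0:
        return LDStats(math.nan, math.nan, math.nan, defined=False)
    D = f.pAB - pA * pB
    if D > 0:
        Dmax = min(pA * pb, pa * pB)
    else:
        Dmax = min(pA * pB, pa * pb)
    Dprime = 0.0 if Dmax == 0 else abs(D) / Dmax
    r2 = D * D / (pA * pa * pB * pb)
    return LDStats(D, min(Dprime, 1.0), min(r2, 1.0), defined=True)


def _pair_stats(
    data: HaplotypeMatrix | GenotypeMatrix, vA: str, vB: str
) -> tuple[LDStats, int, str]:
    if isinstance(data, HaplotypeMatrix):
        f = hap_freqs_phased(data, vA, vB)
    else:
        ia, ib = data.variant_index(vA), data.variant_index(vB)
        ca, cb = data.calls[:, ia, :], data.calls[:, ib, :]
        complete = (ca != MISSING).all(axis=1) & (cb != MISSING).all(axis=1)
        all_phased = bool(
            (data.phased[complete][:, [ia, ib]]).all()
        ) if complete.any() else False
        if all_phased and complete.all():
            f = hap_freqs_phased(to_haplotypes(data), vA, vB)
        else:
            f = hap_freqs_em(data, vA, vB)
    return ld_stats(f), f.n_used, f.method


def ld_profile(
    data: HaplotypeMatrix | GenotypeMatrix,
    lead: str,
    region: tuple[int, int] | None = None,
) -> LDProfile:
    """LD of every variant in ``region`` against one lead variant.

    Phased counting is used when the input allows it; otherwise EM.
    Pairs where LD is undefined (a monomorphic partner) are kept and
    flagged, never silently dropped. A monomorphic lead is an error: its
    profile would be meaningless everywhere.
    """
    il = data.variant_index(lead)
    lead_rec = data.variants[il]
    lead_stats, _, _ = _pair_stats(data, lead, lead)
    if not lead_stats.defined:
        raise ValueError(f"lead variant {lead!r} is monomorphic in the panel")

    entries: dict[str, tuple[int, LDStats]] = {}
    n_used: dict[str, int] = {}
    method: dict[str, str] = {}
    for v in data.variants:
        if region is not None and not (region[0] <= v.pos <= region[1]):
            continue
        if v.chrom != lead_rec.chrom:
            raise ValueError("profile region spans multiple chromosomes")
        stats, n, meth = _pair_stats(data, lead, v.id)
        if v.id == lead:
            stats = LDStats(stats.D, 1.0, 1.0, True)
        entries[v.id] = (v.pos, stats)
        n_used[v.id] = n
        method[v.id] = meth
    return LDProfile(lead_rec, entries, n_used, method)


def write_ld_profile(profile: LDProfile, path: str) -> None:
    """Write a profile as TSV: variant_id, chrom, pos, r2, d_prime, n_used, method."""
    import pandas as pd

    rows = []
    for vid, (pos, s) in sorted(
        profile.entries.items(), key=lambda kv: (kv[1][0], kv[0])
    ):
        rows.append(
            {
                "variant_id": vid,
                "chrom": profile.lead.chrom,
                "pos": pos,
                "r2": s.r2 if s.defined else math.nan,
                "d_prime": s.Dprime if s.defined else math.nan,
                "n_used": (profile.n_used or {}).get(vid, ""),
                "method": (profile.method or {}).get(vid, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
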