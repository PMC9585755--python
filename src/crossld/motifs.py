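"""Allele-aware scanning for splicing-regulatory sequence motifs.

A single-nucleotide variant can create or destroy an RNA-binding-protein
recognition word. The default motif is the Rbfox binding element, the
RNA word GCAUG — scanned here on DNA as GCATG, on both strands. For a
variant with ref and alt alleles, every motif occurrence overlapping the
variant position is located on the reference-allele sequence and on the
alternate-allele sequence, then classified:

    destroyed  — present with the ref base, gone with the alt base
    created    — absent with the ref base, present with the alt base
    retained   — present with both (the variant falls on a degenerate
                 position of the pattern)

IUPAC degeneracy is supported; matching is exact-word (no PWM scoring).
The variant's position within the motif is reported 1-based, counted
along the motif's own 5'→3' direction, so a variant at the third base of
a plus-strand GCATG reads "3".
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for ch in pattern.upper():
        if ch not in _IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern")
        opts = _IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping occurrences are all found
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass(frozen=True)
class MotifDef:
    """An IUPAC DNA motif; Rbfox GCATG by default."""

    name: str = "Rbfox"
    pattern: str = "GCATG"
    scan_both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        _iupac_regex(self.pattern)  # validates alphabet

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class AlleleContext:
    """A reference sequence window around one SNV."""

    sequence: str
    variant_offset: int  # 0-based offset of the variant in the window
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not 0 <= self.variant_offset < len(self.sequence):
            raise ValueError("variant_offset outside sequence window")
        if self.sequence[self.variant_offset].upper() != self.ref.upper():
            raise ValueError(
                f"sequence has {self.sequence[self.variant_offset]!r} at the "
                f"variant offset but ref allele is {self.ref!r} — likely a "
                "coordinate bug"
            )

    def allele_sequence(self, allele: str) -> str:
        seq = self.sequence.upper()
        i = self.variant_offset
        return seq[:i] + allele.upper() + seq[i + 1 :]


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence, classified by its allele dependence.

    ``variant_offset_in_motif`` is 1-based along the motif's 5'→3'
    direction, 0 when the variant lies outside the instance. ``allele``
    names which allele's sequence carries the instance: "ref", "alt", or
    "both".
    """

    motif: str
    start: int  # 0-based window offset of the instance (plus-strand coords)
    strand: str  # "+" or "-"
    allele: str
    variant_offset_in_motif: int
    status: str  # created | destroyed | retained


def _find_instances(
    seq: str, motif: MotifDef
) -> set[tuple[int, str]]:
    """All (start, strand) motif instances in seq (plus-strand coords)."""
    out: set[tuple[int, str]] = set()
    rx = _iupac_regex(motif.pattern)
    for m in rx.finditer(seq):
        out.add((m.start(), "+"))
    if motif.scan_both_strands:
        rc_rx = _iupac_regex(reverse_complement(motif.pattern))
        for m in rc_rx.finditer(seq):
            out.add((m.start(), "-"))
    return out


def _offset_in_motif(
    start: int, strand: str, length: int, variant_offset: int
) -> int:
    """1-based variant position along the motif; 0 if outside."""
    if not start <= variant_offset < start + length:
        return 0
    if strand == "+":
        return variant_offset - start + 1
    return start + length - variant_offset  # read 5'→3' on the minus strand


def classify_disruption(
    ref_hits: set[tuple[int, str]], alt_hits: set[tuple[int, str]]
) -> dict[tuple[int, str], str]:
    """Pair instances by (start, strand) and classify the allele effect."""
    status: dict[tuple[int, str], str] = {}
    for key in ref_hits | alt_hits:
        if key in ref_hits and key in alt_hits:
            status[key] = "retained"
        elif key in ref_hits:
            status[key] = "destroyed"
        else:
            status[key] = "created"
    return status


def scan_motifs(
    ctx: AlleleContext,
    motifs: list[MotifDef] | None = None,
    overlapping_only: bool = True,
) -> list[MotifHit]:
    """Classify every motif instance on the ref and alt sequences.

    By default only instances overlapping the variant are reported — the
    question being asked is the allele's effect, not a motif map of the
    window. Set ``overlapping_only=False`` to also report non-overlapping
    instances (their ``variant_offset_in_motif`` is 0 and their status is
    always "retained" since the alleles agree outside the variant).
    """
    if motifs is None:
        motifs = [MotifDef()]
    hits: list[MotifHit] = []
    for motif in motifs:
        ref_inst = _find_instances(ctx.allele_sequence(ctx.ref), motif)
        alt_inst = _find_instances(ctx.allele_sequence(ctx.alt), motif)
        status = classify_disruption(ref_inst, alt_inst)
        for (start, strand), st in sorted(status.items()):
            off = _offset_in_motif(
                start, strand, len(motif), ctx.variant_offset
            )
            if overlapping_only and off == 0:
                continue
            allele = {"destroyed": "ref", "created": "alt", "retained": "both"}[st]
            hits.append(
                MotifHit(motif.name, start, strand, allele, off, st)
            )
    return hits


def read_motif_list(path: str) -> list[MotifDef]:
    """Read a motif TSV: ``name<TAB>pattern<TAB>both_strands``."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"name", "pattern"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns name, pattern")
    out = []
    for _, row in df.iterrows():
        both = str(row.get("both_strands", "true")).strip().lower() in (
            "1", "true", "yes",
        )
        out.append(MotifDef(row["name"], row["pattern"], both))
    return out


def write_motif_hits(hits: list[MotifHit], path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "motif": h.motif,
                "start": h.start,
                "strand": h.strand,
                "allele": h.allele,
                "variant_offset_in_motif": h.variant_offset_in_motif,
                "status": h.status,
            }
            for h in hits
        ],
        columns=[
            "motif", "start", "strand", "allele",
            "variant_offset_in_motif", "status",
        ],
    ).to_csv(path, sep="\t", index=False)
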