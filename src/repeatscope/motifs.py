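"""Scanning for the conserved unit-start motif and its stem-base partner.

Repeat units open with a GGGTGTG-like 7-mer; observed field variants
(GGGTGGT, GGGTGGG, GGGTGCG, TGGTGTG) are all within Hamming distance 2
of the canonical form, which sets the default mismatch budget. At the
base of a repeat hairpin the motif on the 5' strand faces its reverse
complement on the 3' strand; the palindrome check verifies that,
treating G.U as complementary in RNA context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .fold import Hairpin

__all__ = [
    "CANONICAL_MOTIF",
    "MotifHit",
    "scan_motif",
    "stem_base_motif_check",
    "unit_motif_hits",
]

CANONICAL_MOTIF = "GGGTGTG"

Context = Literal["unit_5prime", "stem_base_5p", "stem_base_3p", "other"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}
# allowed partner bases when G.U wobble counts as complementary
_WOBBLE_PARTNERS = {
    "A": {"T", "U"},
    "C": {"G"},
    "G": {"C", "T", "U"},
    "T": {"A", "G"},
    "U": {"A", "G"},
}


@dataclass(frozen=True)
class MotifHit:
    pattern: str
    position: int
    mismatches: int
    context: Context = "other"


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def scan_motif(
    seq: str,
    canonical: str = CANONICAL_MOTIF,
    max_mismatch: int = 2,
    context: Context = "other",
) -> list[MotifHit]:
    """All windows within ``max_mismatch`` of the canonical motif.

    Overlapping hits are allowed; output is sorted by position, then by
    distance. T and U are interchangeable.
    """
    seq = seq.upper().replace("U", "T")
    canonical = canonical.upper().replace("U", "T")
    w = len(canonical)
    hits = []
    for i in range(len(seq) - w + 1):
        d = hamming(seq[i : i + w], canonical)
        if d <= max_mismatch:
            hits.append(MotifHit(pattern=seq[i : i + w], position=i, mismatches=d,
                                 context=context))
    hits.sort(key=lambda h: (h.position, h.mismatches))
    return hits


def unit_motif_hits(
    unit_seqs: Sequence[str],
    canonical: str = CANONICAL_MOTIF,
    max_mismatch: int = 2,
    window: int = 10,
) -> list[MotifHit | None]:
    """Best 5'-end motif hit per unit (within ``window`` nt of its start)."""
    out: list[MotifHit | None] = []
    for seq in unit_seqs:
        hits = [h for h in scan_motif(seq, canonical, max_mismatch, "unit_5prime")
                if h.position < window]
        out.append(min(hits, key=lambda h: (h.mismatches, h.position)) if hits else None)
    return out


def _wobble_complement_match(pattern: str, partner_rc_window: str, budget: int) -> bool:
    """Is the reverse complement of ``pattern`` within ``budget`` of some
    window, counting G.U partners as complementary?"""
    pattern = pattern.upper().replace("U", "T")
    w = len(pattern)
    window = partner_rc_window.upper()
    for i in range(len(window) - w + 1):
        sub = window[i : i + w]
        # pattern read 5'->3' pairs antiparallel with sub read 3'->5'
        mism = sum(
            1
            for a, b in zip(pattern, reversed(sub))
            if b.replace("U", "T") not in {p.replace("U", "T") for p in _WOBBLE_PARTNERS[a]}
        )
        if mism <= budget:
            return True
    return False


def stem_base_motif_check(
    hairpin: "Hairpin",
    seq: str,
    canonical: str = CANONICAL_MOTIF,
    max_mismatch: int = 2,
    window: int = 10,
) -> tuple[MotifHit | None, bool]:
    """Motif at the 5' stem base, palindromic partner at the 3' base.

    Searches a ``window``-nt region around the 5' base strand for a
    motif hit; when found, checks whether the corresponding 3' base
    strand window contains its reverse complement (same mismatch
    budget, G.U allowed).
    """
    seq = seq.upper()
    b5 = hairpin.base_interval_5p
    b3 = hairpin.base_interval_3p
    lo5 = max(0, b5.start - window // 2)
    hi5 = min(len(seq), b5.start + window + len(canonical))
    region5 = seq[lo5:hi5]
    hits = scan_motif(region5, canonical, max_mismatch, "stem_base_5p")
    if not hits:
        return None, False
    best = min(hits, key=lambda h: (h.mismatches, h.position))
    hit = MotifHit(
        pattern=best.pattern,
        position=lo5 + best.position,
        mismatches=best.mismatches,
        context="stem_base_5p",
    )
    lo3 = max(0, b3.end - window - len(canonical))
    hi3 = min(len(seq), b3.end + window // 2)
    region3 = seq[lo3:hi3]
    return hit, _wobble_complement_match(hit.pattern, region3, max_mismatch)
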