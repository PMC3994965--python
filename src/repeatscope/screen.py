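"""Two-criterion pseudogene screen.

A spacer is called functional when (1) its retained coding flanks
(5.8S and 28S termini, ~90 nt in total) carry a low substitution rate
against the reference, and (2) the spacer folds into several long
hairpins in *every* near-optimal secondary structure. Ribosomal
pseudogenes accumulate substitutions freely and lose their compact
stem-loop architecture, so either failure flags a suspect sequence.

Neither criterion has a field-standard numeric cutoff; the defaults
here (flank rate <= 0.05; >= 3 qualifying hairpins, where a qualifying
hairpin has a stem of >= 15 pairs with <= 3 internal loops) are package
choices, calibrated on the synthetic generator so that planted repeat
hairpins qualify while the background folding of random sequence does
not, and are exposed in configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .align import ScoringParams, global_align
from .fold import SecondaryStructure, extract_hairpins
from .seqio import SequenceRecord, SpacerAnnotation

__all__ = [
    "ScreenThresholds",
    "PseudogeneVerdict",
    "ScreeningError",
    "flank_substitution_rate",
    "assess_functionality",
    "count_qualifying_hairpins",
]

#: no free end gaps: the flank hit is compared to the reference end-to-end
_FLANK_SCORING = ScoringParams(match=1, mismatch=-1, gap_open=-2, gap_extend=-1,
                               free_end_gaps=False)


class ScreeningError(ValueError):
    """Missing flank annotation or empty structure set."""


@dataclass(frozen=True)
class ScreenThresholds:
    max_flank_rate: float = 0.05
    min_hairpins: int = 3
    min_stem_pairs: int = 15
    max_internal_loops: int = 3


DEFAULT_THRESHOLDS = ScreenThresholds()

Verdict = Literal["functional", "suspect_pseudogene"]


@dataclass(frozen=True)
class PseudogeneVerdict:
    seq_id: str
    flank_substitution_rate: float
    flank_ok: bool
    hairpins_ok: bool
    verdict: Verdict

    def __post_init__(self) -> None:
        assert (self.verdict == "functional") == (self.flank_ok and self.hairpins_ok)


def flank_substitution_rate(
    rec: SequenceRecord,
    annotation: SpacerAnnotation,
    ref5: str,
    ref3: str,
) -> float:
    """Substitutions per site over both retained coding flanks.

    Each annotated flank is globally aligned to its reference; the rate
    is mismatched columns over compared columns, gap columns excluded,
    pooled across the two flanks.
    """
    if len(annotation.flank5) == 0 or len(annotation.flank3) == 0:
        raise ScreeningError(f"record {rec.id!r}: flank intervals missing")
    mismatches = compared = 0
    for interval, ref in ((annotation.flank5, ref5), (annotation.flank3, ref3)):
        segment = rec.residues[interval.start : interval.end]
        aln = global_align(segment, ref.upper(), _FLANK_SCORING)
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if x == "-" or y == "-":
                continue
            compared += 1
            if x != y:
                mismatches += 1
    if compared == 0:
        raise ScreeningError(f"record {rec.id!r}: no comparable flank columns")
    return mismatches / compared


def count_qualifying_hairpins(
    structure: SecondaryStructure,
    thresholds: ScreenThresholds = DEFAULT_THRESHOLDS,
) -> int:
    """Hairpins with a long enough stem and few enough interruptions."""
    return sum(
        1
        for hp in extract_hairpins(structure, min_stem=thresholds.min_stem_pairs)
        if hp.internal_loops <= thresholds.max_internal_loops
    )


def assess_functionality(
    seq_id: str,
    structures: Sequence[SecondaryStructure],
    rate: float,
    thresholds: ScreenThresholds = DEFAULT_THRESHOLDS,
) -> PseudogeneVerdict:
    """Apply both screen criteria to one spacer.

    ``structures`` is the near-optimal structure set of the ITS2;
    the hairpin criterion requires every one of them to contain at
    least ``min_hairpins`` qualifying hairpins.
    """
    if not structures:
        raise ScreeningError(f"record {seq_id!r}: empty structure list")
    flank_ok = rate <= thresholds.max_flank_rate
    hairpins_ok = all(
        count_qualifying_hairpins(s, thresholds) >= thresholds.min_hairpins
        for s in structures
    )
    return PseudogeneVerdict(
        seq_id=seq_id,
        flank_substitution_rate=rate,
        flank_ok=flank_ok,
        hairpins_ok=hairpins_ok,
        verdict="functional" if (flank_ok and hairpins_ok) else "suspect_pseudogene",
    )
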