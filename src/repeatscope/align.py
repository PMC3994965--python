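"""Pairwise and small-set multiple alignment.

Global alignment (affine gaps, optionally free at the 3' ends, because
indels in the repeat units cluster at their 3' ends) and a center-star
multiple aligner for sets of up to ~20 short, highly similar sequences
such as the repeat units of one spacer. For such inputs center-star is
near-optimal and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from Bio import Align as _BioAlign

__all__ = [
    "ScoringParams",
    "PairwiseAlignment",
    "LocalHit",
    "MultipleAlignment",
    "global_align",
    "local_align",
    "center_star_msa",
    "identity_of",
]

GAP = "-"


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring scheme.

    ``gap_open`` is the score of the first gapped residue, ``gap_extend``
    of each further residue in the same gap. With ``free_end_gaps`` the
    terminal gaps at the right (3') end of either sequence score 0.
    """

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1
    free_end_gaps: bool = True


DEFAULT_SCORING = ScoringParams()


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity: float

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a query inside a target."""

    target_start: int
    target_end: int
    query_start: int
    query_end: int
    score: float
    identity: float
    aligned_target: str = ""
    aligned_query: str = ""


def _make_aligner(params: ScoringParams, mode: str) -> _BioAlign.PairwiseAligner:
    aligner = _BioAlign.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if mode == "global" and params.free_end_gaps:
        if hasattr(aligner, "open_right_insertion_score"):
            aligner.open_right_insertion_score = 0
            aligner.extend_right_insertion_score = 0
            aligner.open_right_deletion_score = 0
            aligner.extend_right_deletion_score = 0
        else:  # Biopython < 1.86 attribute names
            aligner.target_right_open_gap_score = 0
            aligner.target_right_extend_gap_score = 0
            aligner.query_right_open_gap_score = 0
            aligner.query_right_extend_gap_score = 0
    return aligner


def identity_of(aligned_a: str, aligned_b: str, ignore_gaps: bool = False) -> float:
    """Matches over aligned columns, excluding double-gap columns.

    With ``ignore_gaps`` every column containing a gap is excluded, so
    the value reflects substitution distance only — appropriate when
    indels should not count against similarity (e.g. repeat-unit
    typing, where indels concentrate at unit 3' ends).
    """
    cols = matches = 0
    for x, y in zip(aligned_a, aligned_b):
        if x == GAP and y == GAP:
            continue
        if ignore_gaps and (x == GAP or y == GAP):
            continue
        cols += 1
        if x == y:
            matches += 1
    return matches / cols if cols else 0.0


def global_align(a: str, b: str, params: ScoringParams = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal global alignment of two DNA strings.

    Deterministic: of all co-optimal paths the first in the aligner's
    canonical traceback order (diagonal before vertical before
    horizontal) is returned.
    """
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    aligner = _make_aligner(params, "global")
    aln = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=aln.score,
        identity=identity_of(aligned_a, aligned_b),
    )


def local_align(target: str, query: str, params: ScoringParams = DEFAULT_SCORING) -> LocalHit | None:
    """Best local (Smith-Waterman) placement of ``query`` in ``target``."""
    if not target or not query:
        raise ValueError("local_align requires two non-empty sequences")
    aligner = _make_aligner(params, "local")
    alignments = aligner.align(target, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    aligned_t, aligned_q = str(aln[0]), str(aln[1])
    t0, t1 = int(aln.coordinates[0][0]), int(aln.coordinates[0][-1])
    q0, q1 = int(aln.coordinates[1][0]), int(aln.coordinates[1][-1])
    return LocalHit(
        target_start=t0,
        target_end=t1,
        query_start=q0,
        query_end=q1,
        score=aln.score,
        identity=identity_of(aligned_t, aligned_q),
        aligned_target=aligned_t,
        aligned_query=aligned_q,
    )


@dataclass
class MultipleAlignment:
    """Gapped rows of equal length, keyed by sequence id."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"rows of unequal length: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def degapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")

    def column(self, i: int) -> list[str]:
        return [r[i] for r in self.rows.values()]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in self.rows.items():
                fh.write(f">{sid}\n{row}\n")


def _merge_into_master(master_rows: list[list[str]], master_center: list[str],
                       c_aln: str, s_aln: str) -> list[str]:
    """Merge one pairwise (center, seq) alignment into the running MSA.

    'Once a gap, always a gap': gaps already present in the master are
    kept; new gaps required by this pairwise alignment are inserted as
    whole columns into every existing row.
    """
    new_row: list[str] = []
    i = j = 0
    while i < len(master_center) or j < len(c_aln):
        master_gap = i < len(master_center) and master_center[i] == GAP
        pair_gap = j < len(c_aln) and c_aln[j] == GAP
        if master_gap and pair_gap:
            # an existing gap column accommodates this sequence's insertion
            new_row.append(s_aln[j])
            i += 1
            j += 1
        elif master_gap:
            # column inserted for a previous sequence: s gets a gap
            new_row.append(GAP)
            i += 1
        elif j < len(c_aln) and pair_gap:
            # this sequence needs a new column in the master
            master_center.insert(i, GAP)
            for row in master_rows:
                row.insert(i, GAP)
            new_row.append(s_aln[j])
            i += 1
            j += 1
        elif i < len(master_center) and j < len(c_aln):
            new_row.append(s_aln[j])
            i += 1
            j += 1
        elif i < len(master_center):  # pairwise exhausted (should not happen)
            new_row.append(GAP)
            i += 1
        else:  # master exhausted
            master_center.append(GAP)
            for row in master_rows:
                row.append(GAP)
            new_row.append(s_aln[j])
            i += 1
            j += 1
    return new_row


def center_star_msa(
    seqs: Sequence[str] | Mapping[str, str],
    params: ScoringParams = DEFAULT_SCORING,
) -> MultipleAlignment:
    """Center-star multiple alignment of 2-20 sequences.

    The center is the sequence maximizing summed pairwise identity to
    the others (ties broken by lowest input index); the remaining
    sequences are merged via their pairwise alignments to the center.
    Deterministic given input order.
    """
    if isinstance(seqs, Mapping):
        ids = list(seqs)
        strings = [seqs[k] for k in ids]
    else:
        strings = list(seqs)
        ids = [f"s{i}" for i in range(len(strings))]
    if len(strings) < 2:
        raise ValueError("center_star_msa requires at least 2 sequences")
    if len(strings) > 20:
        raise ValueError("center_star_msa is intended for <= 20 sequences")
    for sid, s in zip(ids, strings):
        if not s:
            raise ValueError(f"empty sequence {sid!r}")

    n = len(strings)
    pair: dict[tuple[int, int], PairwiseAlignment] = {}
    sums = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(strings[i], strings[j], params)
            pair[i, j] = aln
            sums[i] += aln.identity
            sums[j] += aln.identity
    center = max(range(n), key=lambda i: (sums[i], -i))

    master_center = list(strings[center])
    order = [k for k in range(n) if k != center]
    master_rows: list[list[str]] = []
    new_rows: list[tuple[int, list[str]]] = []
    for k in order:
        if (center, k) in pair:
            aln = pair[center, k]
            c_aln, s_aln = aln.aligned_a, aln.aligned_b
        else:
            aln = pair[k, center]
            c_aln, s_aln = aln.aligned_b, aln.aligned_a
        row = _merge_into_master(master_rows, master_center, c_aln, s_aln)
        master_rows.append(row)
        new_rows.append((k, row))

    rows: dict[str, str] = {}
    by_index = {center: "".join(master_center)}
    for k, row in new_rows:
        by_index[k] = "".join(row)
    for idx in range(n):
        rows[ids[idx]] = by_index[idx]
    return MultipleAlignment(rows=rows)
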