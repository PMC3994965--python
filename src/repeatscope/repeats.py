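"""Tandem-array detection, unit typing and architecture calling.

The detector is a transparent seed-and-extend scheme:

1. exact k-mer self-matches vote for candidate tandem periods — note
   that with two or three interleaved unit types the fundamental period
   is a di- or trimer of units, so offsets up to ~3.5 units are scanned;
2. for each candidate period, a wraparound dynamic program (Smith-
   Waterman against a circularized provisional consensus) tiles the
   sequence into consensus copies; disjoint array segments (e.g. arrays
   interrupted by decayed elements) are recovered by repeated masking;
3. the consensus is refined from phase-consistent full-cycle copies
   and rotated so that the conserved 5' unit motif (GGGTGTG-like)
   defines phase zero, then cut into unit sub-consensi at internal
   motif-anchored boundaries;
4. the spacer is re-tiled with alignment matches of the sub-consensi
   (robust to partial and phase-shifted copies); the best-supported
   candidate period wins, per-type consensi from the detected units
   drive a polishing re-tile, and unit types that evaded every probe
   are recovered by comparing uncovered segments against each other.

Unit similarity types are then assigned by single-linkage clustering of
pairwise alignment identities, and degenerate (non-repeated) elements
are recognized by their intermediate identity to the type consensi.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

from .align import (
    DEFAULT_SCORING,
    ScoringParams,
    center_star_msa,
    global_align,
    identity_of,
    local_align,
)
from .motifs import scan_motif
from .seqio import Interval

__all__ = [
    "RepeatUnit",
    "RepeatType",
    "Architecture",
    "NONREPEATED",
    "find_tandem_array",
    "assign_types",
    "classify_nonrepeated",
]

#: sentinel type id for degenerate, no-longer-recognizable repeat copies
NONREPEATED = "NR"

#: harsh gap costs make the non-repeated-element identity band behave
#: like a positional (Hamming-style) similarity
_NR_SCORING = ScoringParams(match=1, mismatch=-1, gap_open=-8, gap_extend=-8,
                            free_end_gaps=False)

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MASKED = np.int8(-9)


def _typing_identity(a: str, b: str, scoring: ScoringParams) -> float:
    """Matches over the shorter sequence length.

    Tolerant of the short 3'-end indels seen within repeat types
    (a deleted stretch does not count against identity), but not
    inflatable by gappy alignments of unrelated sequences the way a
    gap-column-excluded identity would be.
    """
    aln = global_align(a, b, scoring)
    matches = sum(
        1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-"
    )
    return matches / min(len(a), len(b))


@dataclass
class RepeatUnit:
    """One detected tandem unit on the ITS2-local coordinate system."""

    seq_id: str
    start: int
    end: int
    label: str = ""
    type_id: int | str | None = None
    unit_seq: str = ""
    identity: float = 0.0  # identity to the array consensus (detection pass)

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RepeatType:
    """A similarity class of units, numbered by first occurrence 5'->3'."""

    type_id: int
    members: list[str]
    consensus: str
    unit_length_range: tuple[int, int]


@dataclass
class Architecture:
    """Ordered layout of repeated and non-repeated elements (one spacer)."""

    seq_id: str
    elements: list[RepeatUnit]
    array_span: Interval
    array_fraction: float

    def pattern(self) -> str:
        """Compact type string, e.g. ``"12121212"`` or ``"1NN1212N"``."""
        return "".join(
            "N" if e.type_id == NONREPEATED else str(e.type_id) for e in self.elements
        )


# ---------------------------------------------------------------------------
# candidate periods from k-mer self-matches


def _candidate_periods(
    seq: str, period_range: tuple[int, int], k: int, max_candidates: int = 3
) -> list[tuple[int, int, int, int]]:
    """Offset clusters of exact k-mer self-matches.

    Returns up to ``max_candidates`` tuples (period, votes, span_start,
    span_end). Offsets up to 3.5x the maximum unit length are collected
    so that interleaved-type arrays (fundamental period = several units)
    are seen.
    """
    lo = period_range[0]
    hi = int(3.5 * period_range[1])
    positions: dict[str, list[int]] = collections.defaultdict(list)
    for i in range(len(seq) - k + 1):
        positions[seq[i : i + k]].append(i)
    votes: collections.Counter[int] = collections.Counter()
    support: dict[int, list[int]] = collections.defaultdict(list)
    for pos in positions.values():
        if len(pos) < 2 or len(pos) > 30:
            continue
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                d = pos[b] - pos[a]
                if lo <= d <= hi:
                    votes[d] += 1
                    support[d].append(pos[a])
                    support[d].append(pos[b] + k)
    if not votes:
        return []
    # smooth into clusters of width +-3 and pick peaks greedily
    remaining = dict(votes)
    clusters: list[tuple[int, int, int, int]] = []
    while remaining and len(clusters) < 8:
        center = max(remaining, key=lambda d: (remaining[d], -d))
        near = [d for d in remaining if abs(d - center) <= 5]
        total = sum(remaining[d] for d in near)
        period = int(round(sum(d * remaining[d] for d in near) / total))
        pos_all: list[int] = []
        for d in near:
            pos_all.extend(support[d])
            del remaining[d]
        clusters.append((period, total, min(pos_all), max(pos_all)))
    clusters.sort(key=lambda c: -c[1])
    best_votes = clusters[0][1]
    kept = [c for c in clusters if c[1] >= max(4, 0.25 * best_votes)]
    # prefer shorter periods among comparably supported clusters: a long
    # period is often a harmonic (multiple) of the true one
    kept.sort(key=lambda c: (c[0]))
    return kept[:max_candidates] if len(kept) > max_candidates else kept


# ---------------------------------------------------------------------------
# wraparound Smith-Waterman against a circular consensus


@njit(cache=True)
def _wdp_fill(s, c, match, mismatch, gap):
    m = s.shape[0]
    p = c.shape[0]
    D = np.zeros((m + 1, p + 1), dtype=np.int32)
    trace = np.zeros((m + 1, p + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, p + 1):
            jp = j - 1 if j > 1 else p
            if s[i - 1] < 0 or c[j - 1] < 0:
                sub = np.int32(-(10**6))
            elif s[i - 1] == c[j - 1]:
                sub = match
            else:
                sub = mismatch
            v = np.int32(0)
            t = np.int8(0)
            d = D[i - 1, jp] + sub
            if d > v:
                v = d
                t = np.int8(1)
            u = D[i - 1, j] + gap
            if u > v:
                v = u
                t = np.int8(2)
            if j > 1:  # no left move across the wrap point
                l = D[i, jp] + gap
                if l > v:
                    v = l
                    t = np.int8(3)
            D[i, j] = v
            trace[i, j] = t
            if v > best:
                best = v
                bi = i
                bj = j
    return D, trace, best, bi, bj


@dataclass
class _Path:
    """One traced WDP path: a contiguous array segment."""

    seq_start: int
    seq_end: int
    copy_starts: list[int]  # sequence positions where consensus col 1 begins
    matches: int
    aligned_cols: int
    score: int

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_cols if self.aligned_cols else 0.0


def _trace_path(trace, s_codes, c_codes, bi: int, bj: int, score: int) -> _Path:
    i, j = bi, bj
    copy_starts: list[int] = []
    matches = aligned = 0
    while trace[i, j] != 0:
        t = trace[i, j]
        if t == 1:
            aligned += 1
            if s_codes[i - 1] == c_codes[j - 1]:
                matches += 1
            if j == 1:
                copy_starts.append(i - 1)
            i, j = i - 1, (j - 1 if j > 1 else len(c_codes))
        elif t == 2:
            aligned += 1
            i -= 1
        else:
            aligned += 1
            j = j - 1 if j > 1 else len(c_codes)
    copy_starts.reverse()
    return _Path(
        seq_start=i,
        seq_end=bi,
        copy_starts=copy_starts,
        matches=matches,
        aligned_cols=aligned,
        score=score,
    )


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int8)


def _wdp_segments(
    seq: str,
    consensus: str,
    min_path_score: int = 40,
    max_passes: int = 8,
    match: int = 2,
    mismatch: int = -2,
    gap: int = -4,
) -> list[_Path]:
    """All disjoint positive-scoring tandem segments, best first."""
    s_codes = _encode(seq)
    c_codes = _encode(consensus)
    paths: list[_Path] = []
    for _ in range(max_passes):
        D, trace, best, bi, bj = _wdp_fill(
            s_codes, c_codes, np.int32(match), np.int32(mismatch), np.int32(gap)
        )
        if best < min_path_score:
            break
        path = _trace_path(trace, s_codes, c_codes, bi, bj, int(best))
        paths.append(path)
        s_codes = s_codes.copy()
        s_codes[path.seq_start : path.seq_end] = _MASKED
    paths.sort(key=lambda p: p.seq_start)
    return paths


def _segment_copies(
    path: _Path, min_len: int, interior_only: bool = False
) -> list[tuple[int, int]]:
    """Copy intervals of one path: boundaries at consensus wrap points.

    With ``interior_only`` only segments whose both boundaries are wrap
    points are returned — these are guaranteed to be phase-consistent
    full cycles, unlike the partial segments at the path ends.
    """
    wraps = set(path.copy_starts)
    bounds = sorted({path.seq_start, path.seq_end, *[
        s for s in path.copy_starts if path.seq_start < s < path.seq_end
    ]})
    out = []
    for a, b in zip(bounds, bounds[1:]):
        if b - a < min_len:
            continue
        if interior_only and not (a in wraps and b in wraps):
            continue
        out.append((a, b))
    return out


def _majority_consensus(msa) -> str:
    """Column-majority consensus; gap-majority columns are dropped.

    Ties prefer a base over a gap, then the base of the earliest row
    carrying one of the tied bases (with only two rows this keeps the
    first copy intact instead of scrambling tied columns).
    """
    out = []
    for col in range(msa.length):
        column = msa.column(col)
        counts = collections.Counter(column)
        gap_count = counts.pop("-", 0)
        if not counts:
            continue
        top = max(counts.values())
        if top < gap_count:
            continue
        tied = {b for b, c in counts.items() if c == top}
        best = next(b for b in column if b in tied)
        out.append(best)
    return "".join(out)


def _refined_consensus(
    seq: str,
    copies: Sequence[tuple[int, int]],
    period: int,
    fallback: str,
) -> str:
    """Majority consensus over phase-consistent full-length copies.

    ``copies`` must be interior (wrap-to-wrap) segments, which share
    the provisional consensus phase by construction; those deviating
    >10% from the candidate period are excluded as well. With no
    usable copy the provisional cycle itself (a true subsequence of
    the array) is kept.
    """
    full = [
        seq[a:b]
        for a, b in copies
        if 0.9 * period <= b - a <= 1.1 * period
    ]
    if not full:
        return fallback
    if len(full) == 1:
        return full[0]
    # cap at 12 copies for the consensus build; they are near-identical
    return _majority_consensus(center_star_msa(full[:12]))


def _motif_splits(
    consensus: str, motif: str, period_range: tuple[int, int]
) -> list[int]:
    """Unit boundaries inside a multi-unit (interleaved-type) consensus.

    Candidate boundaries are motif hits (<= 2 mismatches); a partition
    of the consensus is chosen by dynamic programming so that every
    segment length stays within a tolerant unit-length band, minimizing
    total motif mismatches (chance 2-mismatch hits lose to genuine
    ones), then the number of cuts. Returns interior cut positions; an
    empty list means the consensus is a single unit.
    """
    L = len(consensus)
    lo_u = int(0.7 * period_range[0])
    hi_u = int(1.3 * period_range[1])
    if L <= hi_u:
        return []
    hits = {h.position: h.mismatches for h in scan_motif(consensus, motif, max_mismatch=2)}
    nodes = sorted({0, L} | {p for p in hits if 0 < p < L})
    # DP over nodes: best (sum mismatches, cuts) path from 0 with steps in band
    INF = (10**9, 10**9)
    best: dict[int, tuple[int, int]] = {0: (0, 0)}
    back: dict[int, int] = {}
    for pos in nodes[1:]:
        choice = INF
        origin = -1
        for prev in nodes:
            if prev >= pos:
                break
            if not (lo_u <= pos - prev <= hi_u):
                continue
            b = best.get(prev)
            if b is None:
                continue
            cand = (b[0] + hits.get(pos, 0), b[1] + 1)
            if cand < choice:
                choice = cand
                origin = prev
        if origin >= 0:
            best[pos] = choice
            back[pos] = origin
    if L not in best:
        # no motif-consistent partition (e.g. the motif decayed in a
        # sparse consensus): fall back to equal division
        u = max(2, round(L / (0.5 * (period_range[0] + period_range[1]))))
        return [round(i * L / u) for i in range(1, u)]
    cuts: list[int] = []
    pos = L
    while pos != 0:
        pos = back[pos]
        if pos != 0:
            cuts.append(pos)
    cuts.sort()
    return cuts


def _rotate_to_motif(consensus: str, motif: str) -> str:
    hits = scan_motif(consensus, motif, max_mismatch=2)
    if not hits:
        return consensus
    best = min(hits, key=lambda h: (h.mismatches, h.position))
    return consensus[best.position :] + consensus[: best.position]


def _split_copy(
    seq: str,
    copy: tuple[int, int],
    consensus: str,
    cuts: list[int],
    params: ScoringParams,
    min_unit: int,
) -> list[tuple[int, int]]:
    """Map consensus unit boundaries into one copy's coordinates.

    The copy (possibly a partial or phase-shifted cycle) is locally
    aligned against the doubled consensus; boundary positions (mod the
    consensus length) falling inside the aligned region are projected
    onto the copy.
    """
    if not cuts:
        return [copy]
    a, b = copy
    L = len(consensus)
    boundary_set = {0, *cuts}
    hit = local_align(consensus + consensus, seq[a:b], params)
    if hit is None:
        return [copy]
    mapped: list[int] = []
    cons_pos, copy_pos = hit.target_start, hit.query_start
    for x, y in zip(hit.aligned_target, hit.aligned_query):
        if x != "-" and (cons_pos % L) in boundary_set and y != "-":
            mapped.append(a + copy_pos)
        if x != "-":
            cons_pos += 1
        if y != "-":
            copy_pos += 1
    bounds = sorted({a, b, *[m for m in mapped if a < m < b]})
    out = []
    for x, y in zip(bounds, bounds[1:]):
        if y - x >= min_unit:
            out.append((x, y))
        elif out:  # merge a short remainder into the previous segment
            out[-1] = (out[-1][0], y)
    return out


def _profile_tile(
    its2: str,
    sub_seqs: Sequence[str],
    min_identity: float,
    seq_id: str,
) -> list[RepeatUnit]:
    """Tile the spacer with unit-consensus matches.

    Each sub-consensus is matched repeatedly by local alignment with
    masking; the non-overlapping hit set is selected greedily by
    identity, and small inter-unit gaps (diverged unit 3' tails that
    the local alignment trimmed) are absorbed into the upstream unit,
    matching the 3' bias of real unit-length variation.
    """
    hits: list[tuple[float, int, int]] = []
    for sub in sub_seqs:
        masked = list(its2)
        min_len = int(0.75 * len(sub))
        for _ in range(30):
            hit = local_align("".join(masked), sub)
            if hit is None or hit.target_end - hit.target_start < min_len:
                break
            if hit.identity < min_identity - 0.05:
                break
            hits.append((hit.identity, hit.target_start, hit.target_end))
            for x in range(hit.target_start, hit.target_end):
                masked[x] = "X"
    hits.sort(key=lambda h: (-h[0], h[1]))
    chosen: list[list[int | float]] = []
    for ident, a, b in hits:
        overlap = sum(
            max(0, min(b, cb) - max(a, ca)) for _, ca, cb in chosen
        )
        if overlap > 0.15 * (b - a):
            continue
        chosen.append([ident, a, b])
    chosen.sort(key=lambda h: h[1])
    # trim residual overlaps, then absorb small 3' gaps upstream
    for prev, cur in zip(chosen, chosen[1:]):
        if cur[1] < prev[2]:
            cur[1] = prev[2]
        elif 0 < cur[1] - prev[2] <= 12:
            prev[2] = cur[1]
    units = []
    for ident, a, b in chosen:
        if b <= a:
            continue
        units.append(
            RepeatUnit(
                seq_id=seq_id, start=a, end=b, unit_seq=its2[a:b], identity=ident
            )
        )
    return units


def find_tandem_array(
    its2: str,
    period_range: tuple[int, int] = (80, 130),
    min_copies: int = 3,
    kmer: int = 13,
    min_identity: float = 0.60,
    motif: str = "GGGTGTG",
    seq_id: str = "",
    scoring: ScoringParams = DEFAULT_SCORING,
) -> list[RepeatUnit]:
    """Detect the central tandem-repeat array and segment it into units.

    ``period_range`` bounds the *unit* length; the underlying tandem
    period may be a small multiple of it when similarity types are
    interleaved, so candidate periods up to ~3.5 units are considered.
    For each candidate the wraparound DP yields a refined, motif-phased
    cycle consensus, which is cut into unit sub-consensi; the spacer is
    then tiled with their alignment matches. The candidate maximizing
    the summed identity margin over ``min_identity`` wins, with a 5%
    advantage required before a longer period replaces a shorter one
    (longer periods are often harmonics). Returns untyped units
    labelled A, B, C, ... 5'->3' (empty list when no array is found).
    Deterministic.
    """
    its2 = its2.upper()
    min_unit = int(0.6 * period_range[0])
    candidates = _candidate_periods(its2, period_range, kmer)
    best_units: list[RepeatUnit] = []
    best_score = 0.0
    for period, _votes, span_lo, span_hi in candidates:
        if period > len(its2) // 2:
            continue
        # provisional consensus: one period drawn from the middle of the
        # k-mer support span
        mid = max(span_lo, min((span_lo + span_hi - period) // 2, len(its2) - period))
        provisional = its2[mid : mid + period]
        paths = _wdp_segments(its2, provisional)
        copies: list[tuple[int, int]] = []
        interior: list[tuple[int, int]] = []
        for p in paths:
            copies.extend(_segment_copies(p, min_unit))
            interior.extend(_segment_copies(p, min_unit, interior_only=True))
        if len(copies) < 2:
            continue
        consensus = _rotate_to_motif(
            _refined_consensus(its2, interior, period, provisional), motif
        )
        cuts = _motif_splits(consensus, motif, period_range)
        sub_bounds = [0] + cuts + [len(consensus)]
        sub_seqs = [
            consensus[a:b] for a, b in zip(sub_bounds, sub_bounds[1:]) if b - a >= min_unit
        ] or [consensus]
        units = [
            u for u in _profile_tile(its2, sub_seqs, min_identity, seq_id)
            if u.identity >= min_identity and len(u) >= min_unit
        ]
        if len(units) < min_copies:
            continue
        # identity margin above the floor, summed over units: rewards
        # both copy number and closeness to the consensus, so decayed
        # near-threshold segments cannot outweigh genuine copies
        score = sum(u.identity - min_identity for u in units)
        if score > 1.05 * best_score:
            best_score = score
            best_units = units
    # polish: rebuild per-type consensi from the detected units and
    # re-tile with them. Multi-member similarity classes give much
    # cleaner unit consensi than halves of the cycle consensus (which
    # can be phase-shifted or polluted by decayed elements); two
    # rounds reach a fixed point in practice
    for _ in range(2):
        if not best_units:
            break
        consensi = _cluster_consensi(best_units, scoring=scoring)
        if not consensi:
            break
        units = [
            u for u in _profile_tile(its2, consensi, min_identity, seq_id)
            if u.identity >= min_identity and len(u) >= min_unit
        ]
        if len(units) < min_copies or [
            (u.start, u.end) for u in units
        ] == [(u.start, u.end) for u in best_units]:
            break
        best_units = units
    best_units = _complete_from_gaps(its2, best_units, min_identity, min_unit, seq_id,
                                     scoring)
    for idx, u in enumerate(best_units):
        u.label = _letter(idx)
    return best_units


def _complete_from_gaps(
    its2: str,
    units: list[RepeatUnit],
    min_identity: float,
    min_unit: int,
    seq_id: str,
    scoring: ScoringParams,
) -> list[RepeatUnit]:
    """Recover unit types that evaded every consensus probe.

    A similarity class whose members all fell into uncovered stretches
    (possible when the cycle consensus came out chimeric) is invisible
    to profile tiling — but its members still resemble *each other*.
    Uncovered segments inside and just 3' of the array are therefore
    compared pairwise; a strong mutual match turns both matched
    subintervals into units.
    """
    if not units:
        return units
    units = sorted(units, key=lambda u: u.start)
    median = int(np.median([len(u) for u in units]))
    lo = units[0].start
    hi = min(len(its2), units[-1].end + int(2.5 * median))
    gaps: list[tuple[int, int]] = []
    cursor = lo
    for u in units:
        if u.start - cursor >= int(0.6 * median):
            gaps.append((cursor, u.start))
        cursor = max(cursor, u.end)
    if hi - cursor >= int(0.6 * median):
        gaps.append((cursor, hi))
    new_units: list[RepeatUnit] = []
    for i in range(len(gaps)):
        for j in range(i + 1, len(gaps)):
            (a1, b1), (a2, b2) = gaps[i], gaps[j]
            hit = local_align(its2[a1:b1], its2[a2:b2], scoring)
            if hit is None:
                continue
            span1 = hit.target_end - hit.target_start
            span2 = hit.query_end - hit.query_start
            ident = identity_of(hit.aligned_target, hit.aligned_query, ignore_gaps=True)
            if ident < 0.80 or min(span1, span2) < max(min_unit, 0.75 * median):
                continue
            for start, end in (
                (a1 + hit.target_start, a1 + hit.target_end),
                (a2 + hit.query_start, a2 + hit.query_end),
            ):
                if any(
                    min(end, u.end) - max(start, u.start) > 0.3 * (end - start)
                    for u in units + new_units
                ):
                    continue
                new_units.append(
                    RepeatUnit(
                        seq_id=seq_id,
                        start=start,
                        end=end,
                        unit_seq=its2[start:end],
                        identity=ident,
                    )
                )
    return sorted(units + new_units, key=lambda u: u.start)


def _cluster_consensi(
    units: Sequence[RepeatUnit],
    threshold: float = 0.80,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> list[str]:
    """Majority consensus of each multi-member similarity class."""
    n = len(units)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _typing_identity(units[i].unit_seq, units[j].unit_seq, scoring) >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = collections.defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)
    out = []
    for root in sorted(groups):
        members = groups[root]
        if len(members) < 2:
            # a lone copy still serves as its own probe: re-tiling with
            # it can recruit a homolog that the first pass missed, and
            # decayed elements are sorted out by the identity band later
            out.append(units[members[0]].unit_seq)
        else:
            out.append(
                _majority_consensus(center_star_msa([units[i].unit_seq for i in members]))
            )
    return out


def _letter(idx: int) -> str:
    # A..Z, then AA, AB, ... for pathological inputs
    if idx < 26:
        return chr(ord("A") + idx)
    return _letter(idx // 26 - 1) + chr(ord("A") + idx % 26)


# ---------------------------------------------------------------------------
# typing


def assign_types(
    units: Sequence[RepeatUnit],
    typing_threshold: float = 0.80,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> tuple[list[RepeatUnit], list[RepeatType]]:
    """Cluster units into similarity types by single linkage.

    Two units join one cluster when their global-alignment identity is
    at least ``typing_threshold``; clusters become types numbered by the
    position of their 5'-most member. Units with no partner at the
    threshold are left untyped (candidates for non-repeated elements).
    """
    if not units:
        raise ValueError("assign_types requires at least one unit")
    units = [replace(u) for u in sorted(units, key=lambda u: u.start)]
    n = len(units)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ident = _typing_identity(units[i].unit_seq, units[j].unit_seq, scoring)
            if ident >= typing_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[int]] = collections.defaultdict(list)
    for i in range(n):
        clusters[find(i)].append(i)
    multi = [idx for idx in sorted(clusters) if len(clusters[idx]) >= 2]
    types: list[RepeatType] = []
    for type_id, root in enumerate(multi, start=1):
        members = clusters[root]
        seqs = [units[i].unit_seq for i in members]
        consensus = (
            _majority_consensus(center_star_msa(seqs)) if len(seqs) > 1 else seqs[0]
        )
        lengths = [len(s) for s in seqs]
        for i in members:
            units[i].type_id = type_id
        types.append(
            RepeatType(
                type_id=type_id,
                members=[units[i].label for i in members],
                consensus=consensus,
                unit_length_range=(min(lengths), max(lengths)),
            )
        )
    return units, types


# ---------------------------------------------------------------------------
# architecture with non-repeated elements


def _anchored_identity(
    seq: str, pos: int, limit: int, consensus: str, max_offset: int = 5
) -> tuple[float, int]:
    """Ungapped identity of the consensus anchored near ``pos``.

    A degenerate copy must retain positional (substitution-only)
    similarity; a gapped aligner would let unrelated sequence reach the
    band. Small anchor offsets absorb boundary error of the neighbour
    elements. Returns (identity, window end).
    """
    L = len(consensus)
    best = (0.0, min(pos + L, limit))
    for delta in range(-max_offset, max_offset + 1):
        start = pos + delta
        if start < 0:
            continue
        end = min(start + L, limit, len(seq))
        overlap = end - start
        if overlap < 0.6 * L:
            continue
        window = seq[start:end]
        matches = sum(1 for x, y in zip(window, consensus) if x == y)
        ident = matches / overlap
        if ident > best[0]:
            best = (ident, end)
    return best


def classify_nonrepeated(
    its2: str,
    units: Sequence[RepeatUnit],
    types: Sequence[RepeatType],
    nr_band: tuple[float, float] = (0.40, 0.80),
    scoring: ScoringParams = DEFAULT_SCORING,
    seq_id: str = "",
) -> Architecture:
    """Call degenerate elements and assemble the per-sequence layout.

    Untyped units whose best identity to any type consensus falls in
    ``nr_band`` become non-repeated (NR) elements; below the band they
    are dropped. Uncovered stretches inside and flanking the array are
    scanned for further decayed copies in the same band. Elements are
    relabelled A, B, C, ... in positional order.
    """
    its2 = its2.upper()
    lo, hi = nr_band
    if not units:
        raise ValueError("classify_nonrepeated requires detected units")
    seq_id = seq_id or units[0].seq_id
    consensi = [t.consensus for t in types] or [max(units, key=len).unit_seq]
    unit_len = int(np.median([len(u) for u in units]))

    def best_identity(segment: str) -> float:
        # near-ungapped comparison: a degenerate copy must retain
        # positional similarity, and unrelated sequence then scores
        # ~0.25-0.35, safely below the band floor
        return max(global_align(segment, c, _NR_SCORING).identity for c in consensi)

    elements: list[RepeatUnit] = []
    for u in units:
        if u.type_id is not None:
            elements.append(replace(u))
            continue
        ident = best_identity(u.unit_seq)
        if ident >= hi:
            # rescue: closest type by consensus identity
            best_t = max(
                types, key=lambda t: global_align(u.unit_seq, t.consensus, scoring).identity
            )
            elements.append(replace(u, type_id=best_t.type_id))
        elif ident >= lo:
            elements.append(replace(u, type_id=NONREPEATED, identity=ident))
        # below the band: dropped

    # degenerate elements occur within or 3' of the array, never
    # upstream of the first intact unit: drop 5'-side NR calls
    first_typed = min(
        (e.start for e in elements if e.type_id != NONREPEATED), default=None
    )
    if first_typed is not None:
        elements = [
            e for e in elements
            if e.type_id != NONREPEATED or e.start >= first_typed
        ]

    # scan uncovered stretches inside the array and on its 3' side for
    # decayed copies (degenerate elements sit at or within the 3' part
    # of the array, not upstream of it)
    if elements:
        last = max(e.end for e in elements)
        region_hi = min(len(its2), last + int(2.2 * unit_len))
        covered = sorted((e.start, e.end) for e in elements)
        gaps: list[tuple[int, int]] = []
        cursor = covered[0][1]
        for a, b in covered[1:]:
            if a - cursor >= int(0.6 * unit_len):
                gaps.append((cursor, a))
            cursor = max(cursor, b)
        if region_hi - cursor >= int(0.6 * unit_len):
            gaps.append((cursor, region_hi))
        for ga, gb in gaps:
            pos = ga
            while gb - pos >= int(0.6 * unit_len):
                best = None
                for c in consensi:
                    ident, end = _anchored_identity(its2, pos, min(gb, len(its2)), c)
                    if best is None or ident > best[0]:
                        best = (ident, end)
                ident, seg_end = best
                if lo <= ident < hi:
                    elements.append(
                        RepeatUnit(
                            seq_id=seq_id,
                            start=pos,
                            end=seg_end,
                            type_id=NONREPEATED,
                            unit_seq=its2[pos:seg_end],
                            identity=ident,
                        )
                    )
                    pos = seg_end
                else:
                    pos += unit_len

    elements.sort(key=lambda e: e.start)
    # deduplicate any scan window overlapping a detected element
    pruned: list[RepeatUnit] = []
    for e in elements:
        if e.type_id == NONREPEATED and any(
            o is not e and min(o.end, e.end) - max(o.start, e.start) > 0.3 * len(e)
            for o in elements
        ):
            overlapping = [
                o for o in elements
                if o is not e and min(o.end, e.end) - max(o.start, e.start) > 0.3 * len(e)
            ]
            if any(o.type_id != NONREPEATED or o.identity > e.identity for o in overlapping):
                continue
        pruned.append(e)
    elements = pruned
    for idx, e in enumerate(elements):
        e.label = _letter(idx)
    span = Interval(elements[0].start, elements[-1].end)
    return Architecture(
        seq_id=seq_id,
        elements=elements,
        array_span=span,
        array_fraction=len(span) / len(its2),
    )
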