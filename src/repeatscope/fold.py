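"""RNA secondary-structure prediction and hairpin extraction.

The folding model is a weighted Nussinov dynamic program: each base
pair contributes a score (G-C 3, A-U 2, G-U 1) and each pair stacked
directly on another contributes a stacking bonus. It is *not* a
thermodynamic (Turner) model and its score is not a free energy; the
analyses built on it depend only on the presence and robustness of
hairpins, which this model captures, not on absolute energies.

Near-optimal structures are enumerated best-first (Wuchty-style) down
to a configurable fraction of the optimum, mirroring web-server style
"suboptimal folding" output.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import Interval

__all__ = [
    "FoldParams",
    "SecondaryStructure",
    "Hairpin",
    "fold_mfe",
    "suboptimal_structures",
    "extract_hairpins",
    "pairs_to_dot_bracket",
    "parse_dot_bracket",
]

_NEG = -(10**6)

#: shortest sequence able to close one hairpin loop
_MIN_FOLD_LEN = 5

# base encoding used by the DP kernel
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class FoldParams:
    """Parameters of the simplified folding model.

    ``temperature_note`` is provenance only: the score model has no
    temperature dependence. ``suboptimal_fraction`` f keeps structures
    scoring at least (1-f) times the optimum.
    """

    temperature_note: str = "37C"
    suboptimal_fraction: float = 0.05
    min_hairpin_loop: int = 3
    pair_score_gc: int = 3
    pair_score_au: int = 2
    pair_score_gu: int = 1
    stack_bonus: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.suboptimal_fraction <= 0.2):
            raise ValueError("suboptimal_fraction must lie in [0, 0.2]")
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")


DEFAULT_FOLD_PARAMS = FoldParams()


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free structure: pair list, dot-bracket and score."""

    seq: str  # RNA alphabet
    pairs: tuple[tuple[int, int], ...]
    dot_bracket: str
    score: int

    def validate(self, min_hairpin_loop: int = 3) -> None:
        """Check nesting, pairing uniqueness and minimum loop size."""
        used: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < len(self.seq)):
                raise ValueError(f"pair ({i},{j}) out of range")
            if j - i - 1 < min_hairpin_loop:
                raise ValueError(f"pair ({i},{j}) closes a short loop")
            if i in used or j in used:
                raise ValueError(f"index reused in pair ({i},{j})")
            used.update((i, j))
        for a, b in self.pairs:
            for c, d in self.pairs:
                if a < c < b < d:
                    raise ValueError(f"pseudoknot: ({a},{b}) crosses ({c},{d})")
        if self.dot_bracket != pairs_to_dot_bracket(self.pairs, len(self.seq)):
            raise ValueError("dot_bracket inconsistent with pairs")


@dataclass(frozen=True)
class Hairpin:
    """A maximal stem-loop: pairs from stem base to apex."""

    stem: tuple[tuple[int, int], ...]  # base -> apex
    terminal_loop: Interval
    internal_loops: int
    base_interval_5p: Interval
    base_interval_3p: Interval

    @property
    def stem_length(self) -> int:
        return len(self.stem)


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        # ambiguity codes never pair in this model; encode as -1
        return np.array([_CODE.get(b, -1) for b in seq], dtype=np.int8)


@njit(cache=True)
def _pair_score(a: np.int8, b: np.int8, gc: np.int32, au: np.int32, gu: np.int32) -> np.int32:
    if (a == 2 and b == 1) or (a == 1 and b == 2):
        return gc
    if (a == 0 and b == 3) or (a == 3 and b == 0):
        return au
    if (a == 2 and b == 3) or (a == 3 and b == 2):
        return gu
    return np.int32(-(10**6))


@njit(cache=True)
def _fill(codes, h, gc, au, gu, stack):
    n = codes.shape[0]
    M = np.zeros((n, n), dtype=np.int32)
    P = np.full((n, n), np.int32(-(10**6)), dtype=np.int32)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            if span - 1 >= h and codes[i] >= 0 and codes[j] >= 0:
                s = _pair_score(codes[i], codes[j], gc, au, gu)
                if s > 0:
                    inner = M[i + 1, j - 1] if j - 1 >= i + 1 else np.int32(0)
                    if j - 1 >= i + 1 and P[i + 1, j - 1] + stack > inner:
                        inner = P[i + 1, j - 1] + stack
                    P[i, j] = s + inner
            best = M[i, j - 1]
            for k in range(i, j - h):
                pk = P[k, j]
                if pk > -(10**5):
                    left = M[i, k - 1] if k > i else 0
                    v = left + pk
                    if v > best:
                        best = v
            M[i, j] = best
    return M, P


class _Fold:
    """Filled DP matrices plus traceback helpers for one sequence."""

    def __init__(self, seq: str, params: FoldParams):
        self.rna = _to_rna(seq)
        self.params = params
        self.codes = _encode(self.rna)
        self.M, self.P = _fill(
            self.codes,
            params.min_hairpin_loop,
            np.int32(params.pair_score_gc),
            np.int32(params.pair_score_au),
            np.int32(params.pair_score_gu),
            np.int32(params.stack_bonus),
        )
        self.n = len(self.rna)

    def pairable(self, i: int, j: int) -> bool:
        return self.P[i, j] > _NEG // 2

    def s(self, i: int, j: int) -> int:
        return int(
            _pair_score(
                self.codes[i], self.codes[j],
                np.int32(self.params.pair_score_gc),
                np.int32(self.params.pair_score_au),
                np.int32(self.params.pair_score_gu),
            )
        )

    def mfe(self) -> int:
        return int(self.M[0, self.n - 1]) if self.n else 0

    def traceback(self) -> list[tuple[int, int]]:
        """One optimal structure: prefer pairing the interval ends, then
        bifurcation at the smallest k, then leaving j unpaired."""
        h = self.params.min_hairpin_loop
        stack_bonus = self.params.stack_bonus
        pairs: list[tuple[int, int]] = []
        work: list[tuple[str, int, int]] = [("M", 0, self.n - 1)]
        while work:
            kind, i, j = work.pop()
            if j <= i:
                continue
            if kind == "P":
                pairs.append((i, j))
                ii, jj = i + 1, j - 1
                if jj - ii - 1 >= h and self.pairable(ii, jj) and (
                    self.P[ii, jj] + stack_bonus >= self.M[ii, jj]
                ):
                    work.append(("P", ii, jj))
                elif jj > ii and self.M[ii, jj] > 0:
                    work.append(("M", ii, jj))
                continue
            target = self.M[i, j]
            if target == 0:
                continue
            if self.pairable(i, j) and self.P[i, j] == target:
                work.append(("P", i, j))
                continue
            done = False
            for k in range(i + 1, j - h):
                if self.pairable(k, j):
                    left = self.M[i, k - 1] if k > i else 0
                    if left + self.P[k, j] == target:
                        work.append(("M", i, k - 1))
                        work.append(("P", k, j))
                        done = True
                        break
            if not done:
                work.append(("M", i, j - 1))
        return sorted(pairs)


def pairs_to_dot_bracket(pairs, n: int) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def parse_dot_bracket(db: str) -> tuple[tuple[int, int], ...]:
    """Pairs from a dot-bracket string (round brackets only)."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, c in enumerate(db):
        if c == "(":
            stack.append(idx)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced bracket at {idx}")
            pairs.append((stack.pop(), idx))
        elif c != ".":
            raise ValueError(f"unexpected character {c!r} at {idx}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return tuple(sorted(pairs))


def fold_mfe(seq: str, params: FoldParams = DEFAULT_FOLD_PARAMS) -> SecondaryStructure:
    """Best-scoring structure under the weighted base-pair model."""
    if len(seq) < _MIN_FOLD_LEN:
        raise ValueError(
            f"sequence of length {len(seq)} is too short to fold (< {_MIN_FOLD_LEN})"
        )
    fold = _Fold(seq, params)
    pairs = tuple(fold.traceback())
    return SecondaryStructure(
        seq=fold.rna,
        pairs=pairs,
        dot_bracket=pairs_to_dot_bracket(pairs, fold.n),
        score=fold.mfe(),
    )


def _cons_to_pairs(cons) -> tuple[tuple[int, int], ...]:
    out = []
    while cons is not None:
        out.append(cons[0])
        cons = cons[1]
    return tuple(sorted(out))


def suboptimal_structures(
    seq: str,
    params: FoldParams = DEFAULT_FOLD_PARAMS,
    max_structures: int = 25,
) -> list[SecondaryStructure]:
    """Distinct structures scoring >= (1 - f) * optimum, best-first.

    Exact best-first enumeration over the DP decomposition; every
    structure is produced once (the decomposition is exclusive), and
    output is capped at ``max_structures``.
    """
    if len(seq) < _MIN_FOLD_LEN:
        raise ValueError(
            f"sequence of length {len(seq)} is too short to fold (< {_MIN_FOLD_LEN})"
        )
    fold = _Fold(seq, params)
    n = fold.n
    mfe = fold.mfe()
    threshold = (1.0 - params.suboptimal_fraction) * mfe
    h = params.min_hairpin_loop
    stack_bonus = params.stack_bonus
    M, P = fold.M, fold.P

    results: list[SecondaryStructure] = []
    seen: set[tuple[tuple[int, int], ...]] = set()
    counter = 0
    # state: (-bound, counter, items, pairs_cons)
    # item: (kind, i, j, bound_contribution, k_lo, k_hi)
    # kind: 0=M, 1=Mx (ends must not pair each other), 2=P, 3=P+stack,
    # 4=Msplit (j pairs with some k in [k_lo, k_hi); expansion takes
    # the best k and re-queues the prefix/suffix ranges, keeping the
    # branching factor constant)
    init_item = (0, 0, n - 1, int(M[0, n - 1]), 0, 0) if n > 1 else None
    init_items = (init_item,) if init_item and init_item[3] > 0 else ()
    heap = [(-mfe, counter, init_items, None)]

    def push(bound, items, pairs_cons):
        # ties pop newest-first (depth-first), so among equally scored
        # states the search drives one structure to completion instead
        # of breadth-first wandering across the whole tie plateau
        nonlocal counter
        if bound + 1e-9 >= threshold:
            counter -= 1
            heapq.heappush(heap, (-bound, counter, items, pairs_cons))

    def split_values(i: int, j: int, k_lo: int, k_hi: int):
        """Bounds of 'j pairs with k' alternatives for k in [k_lo, k_hi)."""
        ks = np.arange(k_lo, k_hi)
        if ks.size == 0:
            return ks, ks
        left = np.where(ks > i, M[i, ks - 1], 0)
        return ks, left + P[ks, j]

    while heap and len(results) < max_structures:
        negbound, _, items, pairs_cons = heapq.heappop(heap)
        bound = -negbound
        if not items:
            pairs = _cons_to_pairs(pairs_cons)
            if pairs not in seen:
                seen.add(pairs)
                results.append(
                    SecondaryStructure(
                        seq=fold.rna,
                        pairs=pairs,
                        dot_bracket=pairs_to_dot_bracket(pairs, n),
                        score=int(round(bound)),
                    )
                )
            continue
        kind, i, j, b, k_lo, k_hi = items[-1]
        rest = items[:-1]
        if kind in (2, 3):  # pair (i, j); decompose the enclosed region
            gain = fold.s(i, j) + (stack_bonus if kind == 3 else 0)
            child_pairs = ((i, j), pairs_cons)
            ii, jj = i + 1, j - 1
            # ends of the inner region mutually paired (stacked helix)
            if jj - ii - 1 >= h and fold.pairable(ii, jj):
                nb = bound - b + gain + int(P[ii, jj]) + stack_bonus
                push(nb, rest + ((3, ii, jj, int(P[ii, jj]) + stack_bonus, 0, 0),),
                     child_pairs)
            # ends not mutually paired
            mx = _mx_bound(M, P, ii, jj, h)
            nb = bound - b + gain + mx
            if mx > 0:
                push(nb, rest + ((1, ii, jj, mx, 0, 0),), child_pairs)
            else:
                push(nb, rest, child_pairs)
            continue
        if kind in (0, 1):  # M/Mx: j unpaired, or j paired with some k
            if j - 1 >= i:
                mleft = int(M[i, j - 1])
                nb = bound - b + mleft
                if mleft > 0:
                    push(nb, rest + ((0, i, j - 1, mleft, 0, 0),), pairs_cons)
                else:
                    push(nb, rest, pairs_cons)
            lo = i if kind == 0 else i + 1
            ks, vals = split_values(i, j, lo, j - h)
            if ks.size:
                best = int(vals.max())
                if best > _NEG // 2:
                    push(bound - b + best,
                         rest + ((4, i, j, best, lo, j - h),), pairs_cons)
            continue
        # kind 4 (Msplit): take the best k in range, re-queue the
        # prefix and suffix sub-ranges as siblings
        ks, vals = split_values(i, j, k_lo, k_hi)
        idx = int(np.argmax(vals))
        k = int(ks[idx])
        pk = int(P[k, j])
        left = int(M[i, k - 1]) if k > i else 0
        new_items = rest
        if k > i and left > 0:
            new_items = new_items + ((0, i, k - 1, left, 0, 0),)
        new_items = new_items + ((2, k, j, pk, 0, 0),)
        push(bound - b + left + pk, new_items, pairs_cons)
        for lo2, hi2 in ((k_lo, k), (k + 1, k_hi)):
            if lo2 >= hi2:
                continue
            sub_ks, sub_vals = split_values(i, j, lo2, hi2)
            sub_best = int(sub_vals.max())
            if sub_best > _NEG // 2:
                push(bound - b + sub_best,
                     rest + ((4, i, j, sub_best, lo2, hi2),), pairs_cons)

    if not results:  # no pair is possible anywhere: the open chain
        results.append(
            SecondaryStructure(seq=fold.rna, pairs=(), dot_bracket="." * n, score=0)
        )
    return results


def _mx_bound(M, P, i: int, j: int, h: int) -> int:
    """Best score on [i, j] among structures not pairing i with j."""
    if j <= i:
        return 0
    best = int(M[i, j - 1])
    for k in range(i + 1, j - h):
        pk = int(P[k, j])
        if pk > _NEG // 2:
            v = int(M[i, k - 1]) + pk
            if v > best:
                best = v
    return best


def extract_hairpins(structure: SecondaryStructure, min_stem: int = 4) -> list[Hairpin]:
    """Maximal stem-loops of the structure.

    Starting from each terminal (hairpin) loop, the stem is walked
    outward through parent pairs until a multiloop or the exterior loop
    is reached; unpaired interruptions on either strand count as
    internal loops. Only stems of at least ``min_stem`` pairs qualify.
    """
    pairs = sorted(structure.pairs)
    children: dict[tuple[int, int] | None, list[tuple[int, int]]] = {None: []}
    parent: dict[tuple[int, int], tuple[int, int] | None] = {}
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        par = stack[-1] if stack else None
        parent[p] = par
        children.setdefault(par, []).append(p)
        children.setdefault(p, [])
        stack.append(p)

    hairpins: list[Hairpin] = []
    for p in pairs:
        if children[p]:
            continue  # not a terminal loop
        stem = [p]
        cur = p
        while True:
            par = parent.get(cur)
            if par is None or len(children[par]) != 1:
                break
            stem.append(par)
            cur = par
        stem.reverse()  # base -> apex
        if len(stem) < min_stem:
            continue
        internal = 0
        for outer, inner in zip(stem, stem[1:]):
            if inner[0] > outer[0] + 1 or inner[1] < outer[1] - 1:
                internal += 1
        base, apex = stem[0], stem[-1]
        hairpins.append(
            Hairpin(
                stem=tuple(stem),
                terminal_loop=Interval(apex[0] + 1, apex[1]),
                internal_loops=internal,
                base_interval_5p=Interval(base[0], apex[0] + 1),
                base_interval_3p=Interval(apex[1], base[1] + 1),
            )
        )
    hairpins.sort(key=lambda hp: hp.stem[0])
    return hairpins
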