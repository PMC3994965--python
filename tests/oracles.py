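"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package implementation: the
alignment oracle enumerates alignments recursively, the folding oracle
enumerates every nested pair set, and the diversity oracle runs the
double loop over pairs and columns.
"""

from __future__ import annotations

import functools
import itertools

PAIR_SCORES = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def enumerate_structures(seq: str, min_loop: int = 3):
    """Every pseudoknot-free pair set over ``seq`` (RNA alphabet)."""

    def gen(idx: tuple[int, ...]):
        if not idx:
            yield frozenset()
            return
        i = idx[0]
        yield from gen(idx[1:])  # i unpaired
        for pos in range(1, len(idx)):
            j = idx[pos]
            if (seq[i], seq[j]) in PAIR_SCORES and j - i - 1 >= min_loop:
                for inner in gen(idx[1:pos]):
                    for outer in gen(idx[pos + 1 :]):
                        yield inner | outer | {(i, j)}

    seen = set()
    for s in gen(tuple(range(len(seq)))):
        if s not in seen:
            seen.add(s)
            yield s


def structure_score(seq: str, pairs) -> int:
    """Pair scores plus one stacking bonus per directly nested pair."""
    pair_set = set(pairs)
    total = sum(PAIR_SCORES[(seq[i], seq[j])] for i, j in pairs)
    total += sum(1 for i, j in pairs if (i + 1, j - 1) in pair_set)
    return total


def best_fold_score(seq: str, min_loop: int = 3) -> int:
    return max(structure_score(seq, p) for p in enumerate_structures(seq, min_loop))


def align_score_bruteforce(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = -2,
    gap_extend: int = -1,
    free_right_gaps: bool = True,
) -> int:
    """Maximum global alignment score by exhaustive recursion.

    State: position in each string plus which sequence the previous
    column gapped (for affine costs). Right-terminal gaps may be free.
    """

    @functools.lru_cache(maxsize=None)
    def rec(i: int, j: int, gap_state: int) -> int:
        if i == len(a) and j == len(b):
            return 0
        best = -(10**9)
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            best = max(best, sub + rec(i + 1, j + 1, 0))
        if i < len(a):  # gap in b
            cost = 0 if (free_right_gaps and j == len(b)) else (
                gap_extend if gap_state == 1 else gap_open
            )
            best = max(best, cost + rec(i + 1, j, 1))
        if j < len(b):  # gap in a
            cost = 0 if (free_right_gaps and i == len(a)) else (
                gap_extend if gap_state == 2 else gap_open
            )
            best = max(best, cost + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


def diversity_bruteforce(rows: list[str]):
    """(S, Pi, L, pi) by complete deletion and double loops."""
    unamb = set("ACGT")
    cols = [
        c for c in range(len(rows[0])) if all(r[c] in unamb for r in rows)
    ]
    L = len(cols)
    S = sum(1 for c in cols if len({r[c] for r in rows}) > 1)
    diffs = []
    for a, b in itertools.combinations(rows, 2):
        diffs.append(sum(1 for c in cols if a[c] != b[c]))
    Pi = sum(diffs) / len(diffs)
    return S, Pi, L, Pi / L if L else float("nan")


def motif_scan_bruteforce(seq: str, motif: str, max_mismatch: int):
    hits = []
    for i in range(len(seq) - len(motif) + 1):
        d = sum(x != y for x, y in zip(seq[i : i + len(motif)], motif))
        if d <= max_mismatch:
            hits.append((i, d))
    return hits


def bipartitions_bruteforce(newick_tree, leaves: list[str]):
    """All subsets separated by an edge, by testing every subset.

    Only feasible for <= 8 leaves; relies on a membership callback
    ``newick_tree(subset) -> bool`` supplied by the caller.
    """
    out = []
    for r in range(1, len(leaves)):
        for combo in itertools.combinations(leaves, r):
            if newick_tree(frozenset(combo)):
                out.append(frozenset(combo))
    return out
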