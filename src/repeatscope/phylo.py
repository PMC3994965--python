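"""Distance trees of repeat units and monophyly testing.

Units from several species are aligned together, a p-distance matrix is
computed with pairwise deletion, and a neighbor-joining tree is built
with column-bootstrap supports. The biological question served here is
topological: do homologous repeat types cluster across species (as
expected when repeat duplication predates speciation)? Monophyly is
judged on the unrooted tree via its edge bipartitions.

Leaf names follow the convention ``species/label`` (e.g.
``campestris/A``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .align import MultipleAlignment
from .seqio import UNAMBIGUOUS

__all__ = [
    "DistanceTree",
    "DistanceError",
    "p_distance_matrix",
    "nj_tree",
    "is_monophyletic",
    "bipartitions",
]


class DistanceError(ValueError):
    """A pair of rows shares no comparable (gap-free) column."""


@dataclass
class DistanceTree:
    """Unrooted NJ tree with optional bootstrap supports (0-100)."""

    newick: str
    leaves: list[str]
    supports: dict[frozenset[str], float] = field(default_factory=dict)
    _tree: TreeNode | None = None

    @property
    def tree(self) -> TreeNode:
        if self._tree is None:
            self._tree = TreeNode.read(io.StringIO(self.newick))
        return self._tree


def p_distance_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    """Pairwise mismatch proportions with pairwise deletion of gaps."""
    ids = msa.ids
    if len(ids) < 3:
        raise ValueError("p_distance_matrix requires at least 3 rows")
    rows = [msa.rows[k].upper() for k in ids]
    n = len(rows)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            comparable = diffs = 0
            for x, y in zip(a, b):
                if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
                    comparable += 1
                    if x != y:
                        diffs += 1
            if comparable == 0:
                raise DistanceError(f"no comparable sites between {ids[i]!r} and {ids[j]!r}")
            mat[i, j] = mat[j, i] = diffs / comparable
    return DistanceMatrix(mat, ids=ids)


def _canonical(subset: frozenset[str], all_leaves: frozenset[str], ref: str) -> frozenset[str]:
    """Orient a bipartition side away from the reference leaf."""
    return frozenset(all_leaves - subset) if ref in subset else subset


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial edge bipartitions of an unrooted tree.

    Each bipartition is reported as the side not containing the
    alphabetically first leaf.
    """
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            out.add(_canonical(side, leaves, ref))
    return out


def _nj_from_dm(dm: DistanceMatrix) -> TreeNode:
    return _skbio_nj(dm)


def nj_tree(
    dist: DistanceMatrix | None = None,
    *,
    msa: MultipleAlignment | None = None,
    bootstrap_reps: int = 500,
    seed: int = 0,
) -> DistanceTree:
    """Neighbor-joining tree, optionally with column-bootstrap supports.

    Supports require the alignment (columns are resampled with
    replacement, ``bootstrap_reps`` times, seeded); calling with a
    distance matrix alone yields a tree without supports. Negative
    branch lengths arising from non-additive input are clamped to zero
    by the NJ implementation.
    """
    if dist is None:
        if msa is None:
            raise ValueError("nj_tree needs a distance matrix or an alignment")
        dist = p_distance_matrix(msa)
    if len(dist.ids) < 4:
        raise ValueError("nj_tree requires at least 4 leaves")
    tree = _nj_from_dm(dist)
    leaves = sorted(t.name for t in tree.tips())
    supports: dict[frozenset[str], float] = {}
    if msa is not None and bootstrap_reps > 0:
        rng = np.random.default_rng(seed)
        ids = msa.ids
        rows = [msa.rows[k] for k in ids]
        length = msa.length
        counts: dict[frozenset[str], int] = {}
        for _ in range(bootstrap_reps):
            cols = rng.integers(0, length, size=length)
            resampled = MultipleAlignment(
                rows={sid: "".join(row[c] for c in cols) for sid, row in zip(ids, rows)}
            )
            try:
                rep_tree = _nj_from_dm(p_distance_matrix(resampled))
            except DistanceError:
                continue
            for bp in bipartitions(rep_tree):
                counts[bp] = counts.get(bp, 0) + 1
        for bp in bipartitions(tree):
            supports[bp] = 100.0 * counts.get(bp, 0) / bootstrap_reps
        _annotate_supports(tree, supports)
    newick = tree.__str__().strip()
    return DistanceTree(newick=newick, leaves=leaves, supports=supports, _tree=tree)


def _annotate_supports(tree: TreeNode, supports: dict[frozenset[str], float]) -> None:
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            key = _canonical(side, leaves, ref)
            if key in supports:
                node.name = str(int(round(supports[key])))


def is_monophyletic(tree: DistanceTree, leaf_subset: Iterable[str]) -> bool:
    """True iff some edge bipartition separates exactly this subset.

    Unrooted convention: a single leaf and the full leaf set are
    trivially monophyletic; unknown leaves raise ``ValueError``.
    """
    subset = frozenset(leaf_subset)
    if not subset:
        raise ValueError("leaf subset must be non-empty")
    leaves = frozenset(tree.leaves)
    unknown = subset - leaves
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if len(subset) in (1, len(leaves)):
        return True
    if len(subset) == len(leaves) - 1:
        # complement is a single leaf: always a bipartition of an unrooted tree
        return True
    ref = min(leaves)
    return _canonical(subset, leaves, ref) in bipartitions(tree.tree)
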