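import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from repeatscope.align import MultipleAlignment, center_star_msa
from repeatscope.phylo import (
    DistanceError,
    bipartitions,
    is_monophyletic,
    nj_tree,
    p_distance_matrix,
)
from repeatscope.repeats import assign_types, find_tandem_array
from repeatscope.seqio import delimit_its2
from repeatscope.synth import generate_speciation_cohort, species_presets


def msa_of(rows):
    return MultipleAlignment(rows={f"s{i}": r for i, r in enumerate(rows)})


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance_matrix(msa_of(["ACGT"] * 3))
        assert (np.asarray(dm.data) == 0).all()

    def test_hand_counted(self):
        dm = p_distance_matrix(msa_of(["AAAA", "AATT", "AAAA"]))
        assert dm["s0", "s1"] == pytest.approx(0.5)

    def test_pairwise_deletion_skips_gap_columns(self):
        dm = p_distance_matrix(msa_of(["AC-T", "A-GT", "ACGT"]))
        assert dm["s0", "s1"] == 0.0  # only shared columns compared

    def test_no_comparable_sites_raises(self):
        with pytest.raises(DistanceError):
            p_distance_matrix(msa_of(["A---", "-CGT", "ACGT"]))


def _random_additive_tree(n, rng):
    """Random binary tree: returns (names, distance matrix, bipartitions)."""
    names = [f"L{i}" for i in range(n)]
    parent, blen, children = {}, {}, {}
    active, cnt = list(names), 0
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        new = f"N{cnt}"
        cnt += 1
        children[new] = (a, b)
        blen[a] = float(rng.uniform(0.05, 1.0))
        blen[b] = float(rng.uniform(0.05, 1.0))
        parent[a] = parent[b] = new
        active = [x for x in active if x not in (a, b)] + [new]
    root = active[0]

    def leaves_of(x):
        if x in names:
            return [x]
        a, b = children[x]
        return leaves_of(a) + leaves_of(b)

    D = np.zeros((n, n))
    for ii, jj in itertools.combinations(range(n), 2):
        anc = set()
        x = names[ii]
        while True:
            anc.add(x)
            if x == root:
                break
            x = parent[x]
        d = 0.0
        x = names[jj]
        while x not in anc:
            d += blen[x]
            x = parent[x]
        lca = x
        x = names[ii]
        while x != lca:
            d += blen[x]
            x = parent[x]
        D[ii, jj] = D[jj, ii] = d
    ref = min(names)
    allset = frozenset(names)
    bps = set()
    for node in children:
        lv = frozenset(leaves_of(node))
        if 1 < len(lv) < n - 1:
            bps.add(frozenset(allset - lv) if ref in lv else lv)
    return names, D, bps


@pytest.mark.parametrize("seed", range(8))
def test_nj_reconstructs_additive_trees_exactly(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 11))
    names, D, true_bps = _random_additive_tree(n, rng)
    tree = nj_tree(DistanceMatrix(D, ids=names), bootstrap_reps=0)
    assert bipartitions(tree.tree) == true_bps


def test_star_distances_give_weak_supports(rng):
    """Equal distances carry no signal: all supports below 50."""
    n, L = 6, 60
    base = "".join(rng.choice(list("ACGT"), size=L))
    rows = {}
    for i in range(n):
        chars = list(base)
        for p in rng.choice(L, size=8, replace=False):
            chars[p] = str(rng.choice([b for b in "ACGT" if b != chars[p]]))
        rows[f"t{i}"] = "".join(chars)
    tree = nj_tree(msa=MultipleAlignment(rows=rows), bootstrap_reps=200, seed=0)
    assert tree.supports  # some internal edges exist
    assert all(v < 50 for v in tree.supports.values())


@pytest.fixture(scope="module")
def simple_tree():
    D = np.array(
        [
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 2],
            [6, 6, 2, 0],
        ],
        dtype=float,
    )
    return nj_tree(DistanceMatrix(D, ids=["a", "b", "c", "d"]), bootstrap_reps=0)


class TestMonophyly:
    def test_single_leaf_trivially_monophyletic(self, simple_tree):
        assert is_monophyletic(simple_tree, ["a"])

    def test_full_set_trivially_monophyletic(self, simple_tree):
        assert is_monophyletic(simple_tree, ["a", "b", "c", "d"])

    def test_clade_detected(self, simple_tree):
        assert is_monophyletic(simple_tree, ["a", "b"])
        assert is_monophyletic(simple_tree, ["c", "d"])
        assert not is_monophyletic(simple_tree, ["a", "c"])

    def test_unknown_leaf_rejected(self, simple_tree):
        with pytest.raises(ValueError):
            is_monophyletic(simple_tree, ["zz"])

    def test_agrees_with_bruteforce_bipartition_enumeration(self):
        rng = np.random.default_rng(12)
        names, D, true_bps = _random_additive_tree(7, rng)
        tree = nj_tree(DistanceMatrix(D, ids=names), bootstrap_reps=0)
        ref = min(names)
        allset = frozenset(names)
        for r in range(2, 6):
            for combo in itertools.combinations(names, r):
                subset = frozenset(combo)
                canon = frozenset(allset - subset) if ref in subset else subset
                expected = canon in true_bps or len(subset) in (1, 6)
                assert is_monophyletic(tree, subset) == expected


def test_homologous_types_cluster_across_species():
    """With repeat duplication predating speciation, units group by
    type, not by species."""
    spec = species_presets()["clade_i"]
    cohort = generate_speciation_cohort(spec, n_species=2,
                                        species_divergence=0.05, seed=5)
    leaves = {}
    for rec, truth in cohort:
        its2 = delimit_its2(rec, spec.flank5, spec.flank3).its2_seq(rec)
        typed, types = assign_types(find_tandem_array(its2, seq_id=rec.id))
        for u in typed:
            if isinstance(u.type_id, int):
                leaves[f"{rec.id}/{u.label}.{u.type_id}"] = u.unit_seq
    msa = center_star_msa(leaves)
    tree = nj_tree(msa=msa, bootstrap_reps=100, seed=1)
    for t in (1, 2):
        subset = [k for k in leaves if k.endswith(f".{t}")]
        assert len(subset) >= 6
        assert is_monophyletic(tree, subset)
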