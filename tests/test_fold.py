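import numpy as np
import pytest

from oracles import best_fold_score, enumerate_structures, structure_score
from repeatscope.fold import (
    FoldParams,
    extract_hairpins,
    fold_mfe,
    pairs_to_dot_bracket,
    parse_dot_bracket,
    suboptimal_structures,
)


def revcomp_rna(s):
    return "".join({"A": "U", "U": "A", "G": "C", "C": "G"}[b] for b in reversed(s))


def test_triple_gc_hairpin_score():
    # 3 G-C pairs (9) + 2 stacking bonuses = 11
    st = fold_mfe("GGGAAACCC")
    assert st.score == 11
    assert len(st.pairs) == 3


def test_unpairable_sequence_folds_open():
    st = fold_mfe("AAAAAAAAAA")
    assert st.pairs == ()
    assert st.score == 0
    assert st.dot_bracket == "." * 10


def test_planted_perfect_hairpin_recovered(rng):
    arm = "".join(rng.choice(list("ACGU"), size=20))
    seq = arm + "AAAAA" + revcomp_rna(arm)
    st = fold_mfe(seq)
    hairpins = extract_hairpins(st, min_stem=4)
    assert len(hairpins) == 1
    assert hairpins[0].stem_length >= 18  # near-full planted stem


def test_dna_input_transcribed():
    st = fold_mfe("GGGAAACCC".replace("G", "G").replace("C", "C") + "T")
    assert "T" not in st.seq


@pytest.mark.parametrize("seed", range(10))
def test_mfe_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    for _ in range(10):
        n = int(rng.integers(5, 13))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        st = fold_mfe(seq)
        st.validate()
        assert st.score == best_fold_score(seq)
        assert structure_score(seq, st.pairs) == st.score


class TestSuboptimal:
    def test_unique_optimum_yields_single_structure(self):
        subs = suboptimal_structures("GGGAAACCC")
        assert len(subs) == 1
        assert subs[0].score == 11

    def test_all_structures_within_band(self):
        subs = suboptimal_structures(
            "GGGAAACCCGGGAAACCC", FoldParams(suboptimal_fraction=0.05)
        )
        mfe = subs[0].score
        assert all(s.score >= 0.95 * mfe for s in subs)
        assert [s.score for s in subs] == sorted(
            (s.score for s in subs), reverse=True
        )

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(8, 13))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            subs = suboptimal_structures(
                seq, FoldParams(suboptimal_fraction=0.2), max_structures=10_000
            )
            scores = sorted(
                (structure_score(seq, p) for p in enumerate_structures(seq)),
                reverse=True,
            )
            expected = [s for s in scores if s >= 0.8 * scores[0]]
            assert [s.score for s in subs] == expected
            assert len({s.pairs for s in subs}) == len(subs)

    def test_structural_invariants_hold(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGU"), size=200))
        for s in suboptimal_structures(seq, max_structures=15):
            s.validate()

    def test_planted_stem_persists_across_structures(self, rng):
        """A strong planted inverted repeat appears in every
        near-optimal structure, mostly intact."""
        for trial in range(5):
            arm = "".join(rng.choice(list("ACGU"), size=18))
            filler1 = "".join(rng.choice(list("ACGU"), size=40))
            filler2 = "".join(rng.choice(list("ACGU"), size=40))
            seq = filler1 + arm + "AAAAA" + revcomp_rna(arm) + filler2
            subs = suboptimal_structures(seq, max_structures=25)
            lo = len(filler1)
            planted = {(lo + k, lo + 18 + 5 + (18 - 1 - k)) for k in range(18)}
            for s in subs:
                covered = len(planted & set(s.pairs))
                assert covered >= 0.8 * len(planted)


class TestHairpins:
    def test_two_separated_hairpins(self):
        seq = "GGGGAAAACCCC" + "AUAUAU" + "GCGCAAAAGCGC"
        st = fold_mfe(seq)
        hairpins = extract_hairpins(st, min_stem=3)
        assert len(hairpins) == 2

    def test_internal_loops_counted(self):
        # stem interrupted by three planted A.A bubbles
        left = "GGG" + "A" + "GGG" + "A" + "GGG" + "A" + "GGG"
        right = "CCC" + "A" + "CCC" + "A" + "CCC" + "A" + "CCC"
        seq = left + "UUUUU" + right
        st = fold_mfe(seq)
        hairpins = extract_hairpins(st, min_stem=4)
        assert len(hairpins) == 1
        assert hairpins[0].internal_loops == 3

    def test_min_stem_filters_short_stems(self):
        st = fold_mfe("GCGAAAACGC")  # only a 3-pair stem possible
        assert extract_hairpins(st, min_stem=4) == []
        assert len(extract_hairpins(st, min_stem=3)) == 1

    def test_stem_runs_base_to_apex(self, rng):
        arm = "".join(rng.choice(list("GC"), size=10))
        seq = arm + "AAAA" + revcomp_rna(arm)
        hp = extract_hairpins(fold_mfe(seq), min_stem=4)[0]
        outer = hp.stem[0]
        inner = hp.stem[-1]
        assert outer[0] < inner[0] < inner[1] < outer[1]
        assert hp.terminal_loop.start == inner[0] + 1


def test_dot_bracket_round_trip():
    pairs = ((0, 9), (1, 8), (3, 7))
    db = pairs_to_dot_bracket(pairs, 10)
    assert parse_dot_bracket(db) == tuple(sorted(pairs))
    with pytest.raises(ValueError):
        parse_dot_bracket("(()")


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        FoldParams(suboptimal_fraction=0.5)
    with pytest.raises(ValueError):
        FoldParams(min_hairpin_loop=2)
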