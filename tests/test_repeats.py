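import dataclasses

from repeatscope.repeats import (
    NONREPEATED,
    assign_types,
    classify_nonrepeated,
    find_tandem_array,
)
from repeatscope.seqio import delimit_its2
from repeatscope.synth import generate_family, species_presets


def _detect(spec, seed):
    spec = dataclasses.replace(spec, seed=seed)
    rec, truth = generate_family(spec)
    its2 = delimit_its2(rec, spec.flank5, spec.flank3).its2_seq(rec)
    units = find_tandem_array(its2, seq_id=rec.id)
    return its2, units, truth


def test_exact_tandem_copies_at_planted_coordinates(rng):
    unit = "".join(rng.choice(list("ACGT"), size=110))
    left = "".join(rng.choice(list("ACGT"), size=300))
    right = "".join(rng.choice(list("ACGT"), size=300))
    seq = left + unit * 4 + right
    units = find_tandem_array(seq)
    assert len(units) == 4
    starts = [u.start for u in units]
    assert starts == [300 + 110 * i for i in range(4)]
    assert all(u.end - u.start == 110 for u in units)


def test_interleaved_two_type_array_recovered(clade_i_family):
    """Eight units in two interleaved types, boundaries within 3 bp."""
    spec, rec, truth = clade_i_family
    its2 = delimit_its2(rec, spec.flank5, spec.flank3).its2_seq(rec)
    units = find_tandem_array(its2, seq_id=rec.id)
    assert len(units) == 8
    for det, true in zip(units, truth.typed_units()):
        assert abs(det.start - true.start) <= 3
        assert abs(det.end - true.end) <= 3


def test_no_array_in_random_sequence(rng):
    seq = "".join(rng.choice(list("ACGT"), size=1500))
    assert find_tandem_array(seq) == []


def test_detection_is_deterministic(clade_i_family):
    spec, rec, truth = clade_i_family
    its2 = delimit_its2(rec, spec.flank5, spec.flank3).its2_seq(rec)
    a = find_tandem_array(its2, seq_id=rec.id)
    b = find_tandem_array(its2, seq_id=rec.id)
    assert [(u.start, u.end, u.label) for u in a] == [(u.start, u.end, u.label) for u in b]


class TestAssignTypes:
    def test_two_exact_interleaved_classes(self, rng):
        u1 = "".join(rng.choice(list("ACGT"), size=110))
        u2 = "".join(rng.choice(list("ACGT"), size=110))
        seq = (u1 + u2) * 4
        units = find_tandem_array(seq)
        typed, types = assign_types(units)
        assert len(types) == 2
        members = {t.type_id: set(t.members) for t in types}
        assert members[1] == {"A", "C", "E", "G"}
        assert members[2] == {"B", "D", "F", "H"}

    def test_clade_i_like_membership_alternates(self, clade_i_family):
        spec, rec, truth = clade_i_family
        its2 = delimit_its2(rec, spec.flank5, spec.flank3).its2_seq(rec)
        typed, types = assign_types(find_tandem_array(its2))
        assert {frozenset(t.members) for t in types} == {
            frozenset("ACEG"), frozenset("BDFH")
        }

    def test_three_type_membership(self):
        """A 9-unit, 3-type layout groups as {A,E,H}, {C,D,G}, {B,F,I}."""
        spec = species_presets()["vanderwulpi"]
        its2, units, truth = _detect(
            dataclasses.replace(spec, architecture_pattern="132213213",
                                indel_rate_3prime=0.0), 2
        )
        typed, types = assign_types(units)
        got = {frozenset(t.members) for t in types}
        assert got == {frozenset("AEH"), frozenset("CDG"), frozenset("BFI")}

    def test_types_numbered_by_first_occurrence(self, rng):
        u1 = "".join(rng.choice(list("ACGT"), size=100))
        u2 = "".join(rng.choice(list("ACGT"), size=100))
        seq = (u2 + u1) * 3
        typed, types = assign_types(find_tandem_array(seq))
        # the 5'-most unit belongs to type 1 by convention
        first = min(typed, key=lambda u: u.start)
        assert first.type_id == 1

    def test_consensus_identity_invariant(self, clade_i_family):
        spec, rec, truth = clade_i_family
        its2 = delimit_its2(rec, spec.flank5, spec.flank3).its2_seq(rec)
        typed, types = assign_types(find_tandem_array(its2))
        from repeatscope.align import global_align

        for t in types:
            for u in typed:
                if u.type_id == t.type_id:
                    assert global_align(u.unit_seq, t.consensus).identity >= 0.80


class TestArchitecture:
    def test_terminal_decayed_copy_becomes_nr(self):
        spec = dataclasses.replace(species_presets()["campestris"], seed=17)
        rec, truth = generate_family(spec)
        its2 = delimit_its2(rec, spec.flank5, spec.flank3).its2_seq(rec)
        typed, types = assign_types(find_tandem_array(its2, seq_id=rec.id))
        arch = classify_nonrepeated(its2, typed, types, seq_id=rec.id)
        assert arch.pattern() == "1212121N"

    def test_clade_iv_like_five_repeats_three_nr(self):
        spec = dataclasses.replace(species_presets()["clade_iv"], seed=17)
        rec, truth = generate_family(spec)
        its2 = delimit_its2(rec, spec.flank5, spec.flank3).its2_seq(rec)
        typed, types = assign_types(find_tandem_array(its2, seq_id=rec.id))
        arch = classify_nonrepeated(its2, typed, types, seq_id=rec.id)
        assert sum(1 for e in arch.elements if e.type_id != NONREPEATED) == 5
        assert sum(1 for e in arch.elements if e.type_id == NONREPEATED) == 3

    def test_array_fraction_in_band(self, clade_i_family):
        spec, rec, truth = clade_i_family
        its2 = delimit_its2(rec, spec.flank5, spec.flank3).its2_seq(rec)
        typed, types = assign_types(find_tandem_array(its2, seq_id=rec.id))
        arch = classify_nonrepeated(its2, typed, types, seq_id=rec.id)
        assert 0.50 <= arch.array_fraction <= 0.65
        assert 0 < arch.array_fraction < 1

    def test_elements_tile_without_overlap(self, clade_i_family):
        spec, rec, truth = clade_i_family
        its2 = delimit_its2(rec, spec.flank5, spec.flank3).its2_seq(rec)
        typed, types = assign_types(find_tandem_array(its2, seq_id=rec.id))
        arch = classify_nonrepeated(its2, typed, types, seq_id=rec.id)
        for a, b in zip(arch.elements, arch.elements[1:]):
            assert a.end <= b.start
        labels = [e.label for e in arch.elements]
        assert labels == [chr(ord("A") + i) for i in range(len(labels))]
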