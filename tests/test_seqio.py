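import dataclasses

import numpy as np
import pytest

from repeatscope.seqio import (
    BoundaryError,
    FastaFormatError,
    SequenceRecord,
    collapse_haplotypes,
    delimit_its2,
    gc_fraction,
    read_fasta,
    write_fasta,
)
from repeatscope.synth import generate_family, species_presets


def test_read_fasta_single_record(tmp_path):
    p = tmp_path / "one.fa"
    p.write_text(">k2\nACGT\n")
    recs = read_fasta(p)
    assert len(recs) == 1
    assert recs[0].id == "k2"
    assert recs[0].residues == "ACGT"


def test_read_fasta_normalizes_case_and_uracil(tmp_path):
    p = tmp_path / "u.fa"
    p.write_text(">a\nacgu\n")
    assert read_fasta(p)[0].residues == "ACGT"


@pytest.mark.parametrize(
    "content,match",
    [
        ("", "no FASTA records"),
        (">a\nACGT\n>a\nGGCC\n", "duplicate id"),
        (">a\nAC!T\n", "non-IUPAC"),
    ],
)
def test_read_fasta_rejects_malformed_input(tmp_path, content, match):
    p = tmp_path / "bad.fa"
    p.write_text(content)
    with pytest.raises(FastaFormatError, match=match):
        read_fasta(p)


def test_fasta_round_trip_preserves_bytes(tmp_path, rng):
    records = [
        SequenceRecord(id=f"r{i}", residues="".join(rng.choice(list("ACGTN"), size=80)),
                       label="Clade I")
        for i in range(5)
    ]
    out = tmp_path / "out.fa"
    write_fasta(records, out)
    back = read_fasta(out)
    assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in records]
    assert back[0].label == "Clade I"


def test_gc_fraction_excludes_ambiguity_codes():
    assert gc_fraction("GGCC") == 1.0
    assert gc_fraction("ATGC") == 0.5
    assert gc_fraction("ATGCNNRY") == 0.5  # ambiguity codes out of both counts
    assert gc_fraction("NNNN") == 0.0


class TestDelimitITS2:
    def test_exact_flanks_recover_planted_interval(self, rng):
        ref5 = "".join(rng.choice(list("ACGT"), size=45))
        ref3 = "".join(rng.choice(list("ACGT"), size=45))
        spacer = "".join(rng.choice(list("ACGT"), size=1000))
        rec = SequenceRecord(id="x", residues=ref5 + spacer + ref3)
        ann = delimit_its2(rec, ref5, ref3)
        assert ann.its2.start == len(ref5)
        assert ann.its2_length == 1000
        assert ann.flank5_identity == 1.0

    def test_mutated_flanks_within_two_bp(self, rng):
        spec = species_presets()["clade_i"]
        rec, truth = generate_family(dataclasses.replace(spec, seed=8))
        # plant 2 substitutions into each flank copy carried by the record
        res = list(rec.residues)
        res[10] = "A" if res[10] != "A" else "C"
        res[30] = "A" if res[30] != "A" else "C"
        res[-12] = "A" if res[-12] != "A" else "C"
        rec2 = SequenceRecord(id="m", residues="".join(res))
        ann = delimit_its2(rec2, spec.flank5, spec.flank3)
        assert abs(ann.its2.start - truth.its2.start) <= 2
        assert abs(ann.its2.end - truth.its2.end) <= 2

    def test_missing_flank_raises_boundary_error(self, rng):
        ref5 = "".join(rng.choice(list("ACGT"), size=45))
        ref3 = "".join(rng.choice(list("ACGT"), size=45))
        rec = SequenceRecord(
            id="x", residues=ref5 + "".join(rng.choice(list("ACGT"), size=400))
        )
        with pytest.raises(BoundaryError):
            delimit_its2(rec, ref5, ref3)

    def test_gc_counts_spacer_only(self):
        ref5 = "A" * 25 + "C" * 20
        ref3 = "G" * 20 + "T" * 25
        rec = SequenceRecord(id="x", residues=ref5 + "GGGCCC" + "AT" * 30 + ref3)
        ann = delimit_its2(rec, ref5, ref3)
        assert ann.gc_fraction == pytest.approx(6 / 66)


class TestHaplotypes:
    def test_identical_spacers_collapse(self):
        recs = [
            SequenceRecord(id="a", residues="ACGTACGT"),
            SequenceRecord(id="b", residues="ACGTACGT"),
            SequenceRecord(id="c", residues="ACGTACGA"),
        ]
        groups = collapse_haplotypes(recs)
        assert len(groups) == 2
        assert [r.id for r in groups[0]] == ["a", "b"]

    def test_all_distinct_yields_one_group_each(self, rng):
        recs = [
            SequenceRecord(id=f"r{i}", residues="".join(rng.choice(list("ACGT"), size=60)))
            for i in range(20)
        ]
        groups = collapse_haplotypes(recs)
        assert len(groups) == len({r.residues for r in recs})

    def test_count_bounded_by_record_count(self, rng):
        recs = [
            SequenceRecord(id=f"r{i}", residues="".join(rng.choice(list("AC"), size=4)))
            for i in range(12)
        ]
        groups = collapse_haplotypes(recs)
        assert len(groups) <= len(recs)
        assert sum(len(g) for g in groups) == len(recs)

    def test_empty_input(self):
        assert collapse_haplotypes([]) == []
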