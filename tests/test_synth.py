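import dataclasses

import numpy as np
import pytest

from repeatscope.diversity import diversity_stats
from repeatscope.align import center_star_msa
from repeatscope.motifs import scan_motif
from repeatscope.synth import (
    FamilySpec,
    SpecError,
    generate_cohort,
    generate_family,
    generate_speciation_cohort,
    species_presets,
    write_cohort,
)


def test_generation_is_byte_deterministic():
    spec = dataclasses.replace(species_presets()["clade_iii"], seed=21)
    rec1, truth1 = generate_family(spec)
    rec2, truth2 = generate_family(spec)
    assert rec1.residues == rec2.residues
    assert truth1.units == truth2.units


def test_different_seeds_differ():
    spec = species_presets()["clade_i"]
    a, _ = generate_family(dataclasses.replace(spec, seed=1))
    b, _ = generate_family(dataclasses.replace(spec, seed=2))
    assert a.residues != b.residues


def test_zero_divergence_units_byte_identical():
    spec = FamilySpec(
        spacer_length_target=1400,
        architecture_pattern="12121212",
        unit_length={1: 112, 2: 108},
        per_site_divergence={1: 0.0, 2: 0.0},
        motif_mutation_prob=0.0,
        seed=3,
    )
    rec, truth = generate_family(spec)
    spacer = rec.residues[truth.its2.start : truth.its2.end]
    for t in (1, 2):
        seqs = {
            spacer[u.start : u.end] for u in truth.typed_units() if u.type_id == t
        }
        assert len(seqs) == 1


def test_planted_intervals_consistent_with_sequence(clade_i_family):
    spec, rec, truth = clade_i_family
    spacer = rec.residues[truth.its2.start : truth.its2.end]
    assert len(spacer) == spec.spacer_length_target
    for u in truth.units:
        assert 0 <= u.start < u.end <= len(spacer)
    labels = [u.label for u in truth.units]
    assert labels == sorted(labels)


def test_array_fraction_in_target_band():
    for name, spec in species_presets().items():
        rec, truth = generate_family(dataclasses.replace(spec, seed=6))
        assert 0.50 <= truth.array_fraction <= 0.65, name


def test_motif_planted_at_unit_starts(clade_i_family):
    spec, rec, truth = clade_i_family
    spacer = rec.residues[truth.its2.start : truth.its2.end]
    with_motif = 0
    for u in truth.typed_units():
        unit = spacer[u.start : u.end]
        hits = scan_motif(unit[:7], spec.motif, max_mismatch=2)
        with_motif += bool(hits)
    assert with_motif > len(truth.typed_units()) / 2


def test_infeasible_spec_rejected():
    with pytest.raises(SpecError):
        FamilySpec(
            spacer_length_target=500,
            architecture_pattern="1111111111",
            unit_length={1: 110},
            per_site_divergence={1: 0.01},
        )
    with pytest.raises(SpecError):
        FamilySpec(per_site_divergence={1: 0.5, 2: 0.01})


def test_planted_divergence_matches_recovered_pi():
    """Monte-Carlo: families planted at diversity d recover pi ~ d."""
    spec = FamilySpec(
        spacer_length_target=1300,
        architecture_pattern="111111",
        unit_length={1: 110},
        per_site_divergence={1: 0.05},
        seed=0,
    )
    pis = []
    for s in range(30):
        rec, truth = generate_family(dataclasses.replace(spec, seed=s))
        spacer = rec.residues[truth.its2.start : truth.its2.end]
        seqs = [spacer[u.start : u.end] for u in truth.typed_units()]
        pis.append(diversity_stats(center_star_msa(seqs)).pi)
    mean = np.mean(pis)
    se = np.std(pis) / np.sqrt(len(pis))
    assert abs(mean - 0.05) <= 3 * max(se, 1e-3)


class TestCohorts:
    def test_cohort_shape_and_manifest(self, tmp_path):
        specs = [dataclasses.replace(s, seed=9) for s in species_presets().values()]
        cohort = generate_cohort(specs, n_per_spec=2)
        assert len(cohort) == 10
        write_cohort(cohort, tmp_path)
        manifest = (tmp_path / "manifest.tsv").read_text().splitlines()
        assert len(manifest) == 11  # header + 10 rows
        assert (tmp_path / "cohort.fasta").exists()

    def test_cohort_is_deterministic(self):
        specs = [species_presets()["clade_i"]]
        a = generate_cohort(specs, n_per_spec=3)
        b = generate_cohort(specs, n_per_spec=3)
        assert [r.residues for r, _ in a] == [r.residues for r, _ in b]

    def test_speciation_cohort_shares_type_ancestry(self):
        spec = species_presets()["clade_i"]
        cohort = generate_speciation_cohort(spec, n_species=2,
                                            species_divergence=0.04, seed=2)
        assert len(cohort) == 2
        (r1, t1), (r2, t2) = cohort
        # homologous ancestors differ by the species divergence only
        anc1, anc2 = t1.ancestors[1], t2.ancestors[1]
        diffs = sum(x != y for x, y in zip(anc1, anc2))
        assert 0 < diffs / len(anc1) < 0.12
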