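import dataclasses

import numpy as np
import pytest

from repeatscope.synth import FamilySpec, generate_family, species_presets


@pytest.fixture(scope="session")
def clade_i_family():
    """One Clade-I-like family (8 units, 2 interleaved types) with truth."""
    spec = dataclasses.replace(species_presets()["clade_i"], seed=17)
    rec, truth = generate_family(spec)
    return spec, rec, truth


@pytest.fixture
def rng():
    # function-scoped: every test draws the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(20240101)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


@pytest.fixture(scope="session")
def single_type_spec():
    """A plain single-type array: 6 copies of a 110-mer, no divergence."""
    return FamilySpec(
        spacer_length_target=1200,
        architecture_pattern="111111",
        unit_length={1: 110},
        per_site_divergence={1: 0.0},
        indel_rate_3prime=0.0,
        seed=4,
    )
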