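"""Synthetic ITS2 generator with planted ground truth.

Emits spacers that emulate the architecture of the large barbirostris-
group ITS2: a 1.4-1.8 kb spacer whose central 50-65% is an array of
~95-120 bp tandem units in interleaved similarity types, units carrying
a GGGTGTG-like 7-mer at their 5' end and a planted inverted repeat
(hairpin stem), point substitutions within types, optional 3'-biased
indels, decayed non-repeated elements, and near-invariant coding
flanks. Every emitted record comes with the planted coordinates and
parameters, so detection, typing, diversity and screening can be tested
against known truth without any external data.

``per_site_divergence`` is the *expected within-type pairwise
diversity*: each unit is mutated at half that rate from its type
ancestor, so the planted value is directly comparable to the pi
recovered downstream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .seqio import Interval, SequenceRecord

__all__ = [
    "FamilySpec",
    "SyntheticTruth",
    "TruthUnit",
    "SpecError",
    "generate_family",
    "generate_cohort",
    "generate_speciation_cohort",
    "species_presets",
    "DEFAULT_FLANK5",
    "DEFAULT_FLANK3",
]

#: Synthetic stand-ins for the retained 5.8S 3'-terminus and 28S
#: 5'-terminus (45 nt each, ~90 nt of coding sequence in total). These
#: are fixed arbitrary sequences, not the real gene termini.
DEFAULT_FLANK5 = "TACGACTCTCGGCAACGGATATCTCGGCTCTCGCATCGATGAAGA"
DEFAULT_FLANK3 = "CCTCAGTAATGGGATTGCGCACTTGGACGAATTCAAGCTCTTGGG"

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_RC = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SpecError(ValueError):
    """The requested family cannot be realized (e.g. units exceed target)."""


@dataclass(frozen=True)
class FamilySpec:
    """Blueprint of one synthetic spacer family.

    ``architecture_pattern`` is a string over type digits and ``N``
    (non-repeated element), 5'->3', e.g. ``"12121212"`` or
    ``"1NN1212N"``. ``unit_length`` and ``per_site_divergence`` map
    each type digit to its unit length (bp) and expected within-type
    diversity. ``indel_rate_3prime`` is the per-unit probability of one
    <= 6 bp indel within the unit's final 15 bp.
    """

    spacer_length_target: int = 1545
    architecture_pattern: str = "12121212"
    unit_length: Mapping[int, int] = field(default_factory=lambda: {1: 112, 2: 108})
    per_site_divergence: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.01, 2: 0.02}
    )
    indel_rate_3prime: float = 0.0
    motif: str = "GGGTGTG"
    motif_mutation_prob: float = 0.15
    stem_plant: int = 20
    loop_length: int = 5
    nr_identity_range: tuple[float, float] = (0.45, 0.75)
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    gc: float = 0.54
    label: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        digits = {int(c) for c in self.architecture_pattern if c.isdigit()}
        if not digits:
            raise SpecError("architecture_pattern contains no repeat unit")
        missing = digits - set(self.unit_length) | digits - set(self.per_site_divergence)
        if missing:
            raise SpecError(f"no length/divergence for types {sorted(missing)}")
        for t, d in self.per_site_divergence.items():
            if not (0.0 <= d <= 0.2):
                raise SpecError(f"type {t}: divergence {d} outside [0, 0.2]")
        if self.stem_plant and self.stem_plant <= len(self.motif):
            raise SpecError("stem_plant must exceed the motif length")
        for t in digits:
            need = 2 * self.stem_plant + self.loop_length
            if self.unit_length[t] < need + 5:
                raise SpecError(
                    f"type {t}: unit length {self.unit_length[t]} too short for "
                    f"a {self.stem_plant}-bp planted stem"
                )
        if self.array_length() > 0.75 * self.spacer_length_target:
            raise SpecError("planted elements exceed the spacer length target")

    @property
    def n_units(self) -> int:
        return sum(c.isdigit() for c in self.architecture_pattern)

    @property
    def n_types(self) -> int:
        return len({c for c in self.architecture_pattern if c.isdigit()})

    def array_length(self) -> int:
        mean_unit = int(np.mean(list(self.unit_length.values())))
        total = 0
        for c in self.architecture_pattern:
            total += self.unit_length[int(c)] if c.isdigit() else mean_unit
        return total

    def planted_array_fraction(self) -> float:
        return self.array_length() / self.spacer_length_target


@dataclass(frozen=True)
class TruthUnit:
    label: str
    type_id: int | str  # int, or "NR"
    start: int  # spacer-local, 0-based half-open
    end: int

    @property
    def interval(self) -> Interval:
        return Interval(self.start, self.end)


@dataclass
class SyntheticTruth:
    """Planted coordinates and parameters of one generated family."""

    seq_id: str
    its2: Interval  # on the full record (flanks included)
    units: list[TruthUnit]  # spacer-local coordinates, typed + NR
    array_span: Interval
    array_fraction: float
    ancestors: dict[int, str]
    seed: int
    spec: FamilySpec

    def typed_units(self) -> list[TruthUnit]:
        return [u for u in self.units if u.type_id != "NR"]

    def nr_units(self) -> list[TruthUnit]:
        return [u for u in self.units if u.type_id == "NR"]

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["its2"] = list(self.its2)
        payload["array_span"] = list(self.array_span)
        payload["spec"]["unit_length"] = {
            str(k): v for k, v in self.spec.unit_length.items()
        }
        payload["spec"]["per_site_divergence"] = {
            str(k): v for k, v in self.spec.per_site_divergence.items()
        }
        return json.dumps(payload, indent=1)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p)) if length > 0 else ""


def _revcomp(seq: str) -> str:
    return "".join(_RC[b] for b in reversed(seq))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitutions at ``rate`` with transition:transversion 2:1."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        if rng.random() < 2 / 3:
            chars[i] = _TRANSITION[chars[i]]
        else:
            chars[i] = _TRANSVERSIONS[chars[i]][rng.integers(0, 2)]
    return "".join(chars)


def _mutate_to_identity(seq: str, target: float, rng: np.random.Generator) -> str:
    """Substitute enough distinct positions to reach a target identity."""
    k = int(round((1.0 - target) * len(seq)))
    chars = list(seq)
    for i in rng.choice(len(chars), size=min(k, len(chars)), replace=False):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _ancestral_unit(spec: FamilySpec, type_id: int, rng: np.random.Generator) -> str:
    """One type ancestor: 5' motif, planted inverted repeat, random rest."""
    length = spec.unit_length[type_id]
    arm = spec.motif + _random_seq(rng, spec.stem_plant - len(spec.motif), spec.gc)
    loop = _random_seq(rng, spec.loop_length, spec.gc)
    core = arm + loop + _revcomp(arm)
    return core + _random_seq(rng, length - len(core), spec.gc)


def _apply_indel(copy: str, rng: np.random.Generator, gc: float) -> str:
    """One <= 6 bp indel within the final 15 bp of a unit."""
    size = int(rng.integers(1, 7))
    tail = min(15, len(copy) - 1)
    if rng.random() < 0.5 and tail > size:  # deletion
        start = len(copy) - tail + int(rng.integers(0, tail - size + 1))
        return copy[:start] + copy[start + size :]
    start = len(copy) - tail + int(rng.integers(0, tail + 1))
    return copy[:start] + _random_seq(rng, size, gc) + copy[start:]


def generate_family(
    spec: FamilySpec,
    seq_id: str | None = None,
    _ancestors: Mapping[int, str] | None = None,
) -> tuple[SequenceRecord, SyntheticTruth]:
    """Emit one spacer and its planted truth; byte-deterministic in
    (spec, spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    type_ids = sorted({int(c) for c in spec.architecture_pattern if c.isdigit()})
    ancestors = dict(_ancestors) if _ancestors is not None else {
        t: _ancestral_unit(spec, t, rng) for t in type_ids
    }

    elements: list[tuple[int | str, str]] = []
    prev_type = type_ids[0]
    for c in spec.architecture_pattern:
        if c.isdigit():
            t = int(c)
            copy = _mutate(ancestors[t], spec.per_site_divergence[t] / 2.0, rng)
            if rng.random() < spec.motif_mutation_prob:
                pos = int(rng.integers(0, len(spec.motif)))
                alternatives = [b for b in "ACGT" if b != copy[pos]]
                copy = copy[:pos] + alternatives[rng.integers(0, 3)] + copy[pos + 1 :]
            if rng.random() < spec.indel_rate_3prime:
                copy = _apply_indel(copy, rng, spec.gc)
            elements.append((t, copy))
            prev_type = t
        elif c == "N":
            lo, hi = spec.nr_identity_range
            target = float(rng.uniform(lo, hi))
            elements.append(("NR", _mutate_to_identity(ancestors[prev_type], target, rng)))
        elif not c.isspace():
            raise SpecError(f"unexpected pattern character {c!r}")

    array = "".join(seq for _, seq in elements)
    filler_total = spec.spacer_length_target - len(array)
    if filler_total < 20:
        raise SpecError("planted elements leave no room for non-repetitive filler")
    f5_len = filler_total // 2
    spacer = _random_seq(rng, f5_len, spec.gc) + array + _random_seq(
        rng, filler_total - f5_len, spec.gc
    )

    units: list[TruthUnit] = []
    pos = f5_len
    for idx, (type_id, seq) in enumerate(elements):
        units.append(
            TruthUnit(label=_letter(idx), type_id=type_id, start=pos, end=pos + len(seq))
        )
        pos += len(seq)

    residues = spec.flank5 + spacer + spec.flank3
    seq_id = seq_id or f"sim{spec.seed}"
    record = SequenceRecord(
        id=seq_id, residues=residues, label=spec.label or "synthetic", locality="synthetic"
    )
    truth = SyntheticTruth(
        seq_id=seq_id,
        its2=Interval(len(spec.flank5), len(spec.flank5) + len(spacer)),
        units=units,
        array_span=Interval(f5_len, f5_len + len(array)),
        array_fraction=len(array) / len(spacer),
        ancestors=ancestors,
        seed=spec.seed,
        spec=spec,
    )
    return record, truth


def _letter(idx: int) -> str:
    if idx < 26:
        return chr(ord("A") + idx)
    return _letter(idx // 26 - 1) + chr(ord("A") + idx % 26)


def generate_cohort(
    specs: Sequence[FamilySpec],
    n_per_spec: int = 1,
) -> list[tuple[SequenceRecord, SyntheticTruth]]:
    """Independent families per spec, seeds derived as spec.seed + i."""
    if n_per_spec < 1:
        raise ValueError("n_per_spec must be >= 1")
    out = []
    for spec in specs:
        for i in range(n_per_spec):
            derived = replace(spec, seed=spec.seed + i)
            tag = (spec.label or "fam").replace(" ", "_")
            out.append(generate_family(derived, seq_id=f"{tag}.{derived.seed}"))
    return out


def write_cohort(
    cohort: Sequence[tuple[SequenceRecord, SyntheticTruth]],
    outdir: str | Path,
) -> None:
    """FASTA + per-record truth JSON + manifest TSV."""
    from .seqio import write_fasta  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([rec for rec, _ in cohort], outdir / "cohort.fasta")
    lines = ["id\tlabel\tseed\tspacer_length\tn_units\tn_nr\tarray_fraction"]
    for rec, truth in cohort:
        (outdir / f"{rec.id}.truth.json").write_text(truth.to_json())
        lines.append(
            f"{rec.id}\t{rec.label}\t{truth.seed}\t{len(truth.its2)}\t"
            f"{len(truth.typed_units())}\t{len(truth.nr_units())}\t"
            f"{truth.array_fraction:.4f}"
        )
    (outdir / "manifest.tsv").write_text("\n".join(lines) + "\n")


def generate_speciation_cohort(
    spec: FamilySpec,
    n_species: int = 2,
    species_divergence: float = 0.05,
    seed: int = 0,
) -> list[tuple[SequenceRecord, SyntheticTruth]]:
    """Families for several species whose repeat types share one origin.

    Type ancestors are drawn once (the common ancestor, in which the
    duplication into types already happened); each species inherits
    them with species-level substitutions at ``species_divergence``/2
    before per-unit divergence is applied. Homologous types across the
    resulting species are therefore more similar to each other than to
    any other type — the planted analogue of repeat duplication
    predating speciation.
    """
    rng = np.random.default_rng(seed)
    root_spec = replace(spec, seed=seed)
    type_ids = sorted({int(c) for c in spec.architecture_pattern if c.isdigit()})
    root_ancestors = {t: _ancestral_unit(root_spec, t, rng) for t in type_ids}
    out = []
    for s in range(n_species):
        sp_ancestors = {
            t: _mutate(a, species_divergence / 2.0, rng)
            for t, a in root_ancestors.items()
        }
        sp_spec = replace(spec, seed=seed + 1000 + s, label=f"sp{s + 1}")
        out.append(
            generate_family(sp_spec, seq_id=f"sp{s + 1}", _ancestors=sp_ancestors)
        )
    return out


def species_presets() -> dict[str, FamilySpec]:
    """Five family blueprints mirroring the studied species.

    Spacer lengths, unit counts, type memberships, unit lengths and
    within-type diversities follow the published per-species summaries;
    interior versus terminal placement of Clade IV's three decayed
    elements is a modelling choice (typed members there are A, D, F and
    E, G, leaving B, C and the terminal element degenerate).
    """
    return {
        "clade_i": FamilySpec(
            spacer_length_target=1545,
            architecture_pattern="12121212",
            unit_length={1: 112, 2: 108},
            per_site_divergence={1: 0.01, 2: 0.02},
            indel_rate_3prime=0.0,
            label="Clade I",
        ),
        "campestris": FamilySpec(
            spacer_length_target=1519,
            architecture_pattern="1212121N",
            unit_length={1: 111, 2: 112},
            per_site_divergence={1: 0.023, 2: 0.05},
            indel_rate_3prime=0.15,
            label="An. campestris",
        ),
        "vanderwulpi": FamilySpec(
            spacer_length_target=1727,
            architecture_pattern="132213213N",
            unit_length={1: 109, 2: 105, 3: 99},
            per_site_divergence={1: 0.08, 2: 0.04, 3: 0.04},
            indel_rate_3prime=0.2,
            label="An. vanderwulpi",
        ),
        "clade_iii": FamilySpec(
            spacer_length_target=1730,
            architecture_pattern="132213213N",
            unit_length={1: 112, 2: 104, 3: 104},
            per_site_divergence={1: 0.11, 2: 0.05, 3: 0.05},
            indel_rate_3prime=0.2,
            label="Clade III",
        ),
        "clade_iv": FamilySpec(
            spacer_length_target=1583,
            architecture_pattern="1NN1212N",
            unit_length={1: 104, 2: 116},
            per_site_divergence={1: 0.04, 2: 0.14},
            indel_rate_3prime=0.2,
            label="Clade IV",
        ),
    }
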