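"""Sequence input/output and spacer delimitation.

Reads FASTA / GenBank flat files into plain records, locates the ITS2
interval between the retained 5.8S and 28S coding flanks by local
alignment against reference flank segments, and collapses identical
spacers into haplotype groups.

Coordinates are 0-based, half-open throughout; a Table-style length is
always ``end - start``.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .align import ScoringParams, local_align

__all__ = [
    "Interval",
    "SequenceRecord",
    "SpacerAnnotation",
    "FastaFormatError",
    "BoundaryError",
    "OrientationError",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "delimit_its2",
    "gc_fraction",
    "collapse_haplotypes",
]

# IUPAC nucleotide codes accepted in input sequences.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

# Ambiguity codes excluded from GC and pairwise-difference counting.
UNAMBIGUOUS = frozenset("ACGT")


class FastaFormatError(ValueError):
    """Malformed or invalid sequence input (names the offending record)."""


class BoundaryError(ValueError):
    """A flank reference could not be located at the required identity."""


class OrientationError(ValueError):
    """Flank hits overlap or appear in the wrong 5'->3' order."""


class Interval(NamedTuple):
    """0-based half-open interval on a sequence."""

    start: int
    end: int

    def __len__(self) -> int:  # length in bp
        return self.end - self.start


@dataclass
class SequenceRecord:
    """One DNA sequence with identifier and provenance labels.

    Attributes
    ----------
    id : unique accession or sample name.
    residues : uppercase IUPAC DNA string (U already converted to T).
    label : species or clade tag, e.g. ``"Clade I"`` — free text.
    locality : collection locality — free text.
    """

    id: str
    residues: str
    label: str = ""
    locality: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SpacerAnnotation:
    """ITS2 interval plus retained coding flanks on one record."""

    its2: Interval
    flank5: Interval
    flank3: Interval
    its2_length: int = field(init=False)
    gc_fraction: float = field(init=False)
    #: identity of each flank hit to its reference, for screening reports
    flank5_identity: float = 1.0
    flank3_identity: float = 1.0
    _residues: str = ""

    def __post_init__(self) -> None:
        if not (self.flank5.end <= self.its2.start < self.its2.end <= self.flank3.start):
            raise OrientationError(
                f"flank/spacer intervals out of order: "
                f"{self.flank5} / {self.its2} / {self.flank3}"
            )
        self.its2_length = len(self.its2)
        self.gc_fraction = gc_fraction(
            self._residues[self.its2.start : self.its2.end]
        ) if self._residues else 0.0

    def its2_seq(self, record: SequenceRecord) -> str:
        return record.residues[self.its2.start : self.its2.end]


def _normalise(raw: str, rec_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise FastaFormatError(f"record {rec_id!r}: empty sequence")
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file; header token 1 becomes the id.

    Raises :class:`FastaFormatError` for an empty file, duplicate ids or
    non-IUPAC residues, naming the offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio in SeqIO.parse(str(path), "fasta"):
        if bio.id in seen:
            raise FastaFormatError(f"duplicate id {bio.id!r} in {path}")
        seen.add(bio.id)
        records.append(SequenceRecord(id=bio.id, residues=_normalise(str(bio.seq), bio.id),
                                      label=_label_from_description(bio.description)))
    if not records:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def _label_from_description(description: str) -> str:
    # Optional "label=..." key in the description line survives a round trip.
    for token in description.split()[1:]:
        if token.startswith("label="):
            return token[6:].replace("_", " ")
    return ""


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records to FASTA, preserving ids and residues byte-exactly."""
    bios = []
    for rec in records:
        desc = f"label={rec.label.replace(' ', '_')}" if rec.label else ""
        bios.append(_BioRecord(Seq(rec.residues), id=rec.id, description=desc))
    SeqIO.write(bios, str(path), "fasta-2line")


def read_genbank(path: str | Path) -> list[SequenceRecord]:
    """Read one GenBank flat file (possibly multi-record).

    The source organism becomes the label and the country/geo_loc_name
    qualifier, when present, the locality.
    """
    records = []
    for bio in SeqIO.parse(str(path), "genbank"):
        label = bio.annotations.get("organism", "")
        locality = ""
        for feat in bio.features:
            if feat.type == "source":
                q = feat.qualifiers
                locality = (q.get("geo_loc_name") or q.get("country") or [""])[0]
                break
        records.append(
            SequenceRecord(id=bio.id, residues=_normalise(str(bio.seq), bio.id),
                           label=label, locality=locality)
        )
    if not records:
        raise FastaFormatError(f"no GenBank records found in {path}")
    return records


def read_sequence_dir(directory: str | Path) -> list[SequenceRecord]:
    """Read every ``.fa/.fasta/.gb/.gbk`` file in a local directory.

    This is the accession-replay entry point: deposited sequences are
    supplied as local files, never fetched over the network.
    """
    directory = Path(directory)
    records: list[SequenceRecord] = []
    for p in sorted(directory.iterdir()):
        if p.suffix in {".fa", ".fasta", ".fna"}:
            records.extend(read_fasta(p))
        elif p.suffix in {".gb", ".gbk", ".genbank"}:
            records.extend(read_genbank(p))
    ids = [r.id for r in records]
    dup = [i for i, c in collections.Counter(ids).items() if c > 1]
    if dup:
        raise FastaFormatError(f"duplicate ids across files: {dup}")
    return records


def gc_fraction(seq: str) -> float:
    """G+C fraction over unambiguous bases only.

    Ambiguity codes are excluded from both numerator and denominator;
    returns 0.0 for a sequence with no unambiguous base.
    """
    n = sum(1 for b in seq if b in UNAMBIGUOUS)
    if n == 0:
        return 0.0
    gc = seq.count("G") + seq.count("C")
    return gc / n


#: Linear gap scheme used to locate flank references (match +1, mismatch -1,
#: gap -2): the retained coding segments carry occasional substitutions, so
#: exact motif search is not enough.
FLANK_SCORING = ScoringParams(match=1, mismatch=-1, gap_open=-2, gap_extend=-2,
                              free_end_gaps=False)


def delimit_its2(
    rec: SequenceRecord,
    ref5: str,
    ref3: str,
    min_flank_identity: float = 0.80,
) -> SpacerAnnotation:
    """Delimit ITS2 as the interval strictly between the two flank hits.

    ``ref5`` is the terminal segment of 5.8S retained in the amplicon,
    ``ref3`` the initial segment of 28S. Each is located by local
    alignment; a hit below ``min_flank_identity`` raises
    :class:`BoundaryError`, overlapping or inverted hits raise
    :class:`OrientationError`.
    """
    for name, ref in (("ref5", ref5), ("ref3", ref3)):
        if len(ref) < 20:
            raise ValueError(f"{name} must be >= 20 bp (got {len(ref)})")

    def _find(ref: str, which: str) -> "Interval":
        hit = local_align(rec.residues, ref.upper(), FLANK_SCORING)
        coverage = 0.0 if hit is None else (hit.query_end - hit.query_start) / len(ref)
        # a short perfect chance match must not count as a flank: the
        # hit has to cover most of the reference at the identity floor
        if hit is None or hit.identity < min_flank_identity or coverage < 0.6:
            raise BoundaryError(
                f"record {rec.id!r}: {which} flank not found at identity >= "
                f"{min_flank_identity}"
            )
        # extrapolate reference bases the local alignment trimmed off
        start = max(0, hit.target_start - hit.query_start)
        end = min(len(rec.residues), hit.target_end + (len(ref) - hit.query_end))
        return Interval(start, end), hit.identity

    f5, id5 = _find(ref5, "5'")
    f3, id3 = _find(ref3, "3'")
    if f5.end >= f3.start:
        raise OrientationError(
            f"record {rec.id!r}: flank hits overlap or are inverted ({f5} vs {f3})"
        )
    return SpacerAnnotation(
        its2=Interval(f5.end, f3.start),
        flank5=f5,
        flank3=f3,
        flank5_identity=id5,
        flank3_identity=id3,
        _residues=rec.residues,
    )


def collapse_haplotypes(
    records: Sequence[SequenceRecord],
    annotations: Mapping[str, SpacerAnnotation] | None = None,
) -> list[list[SequenceRecord]]:
    """Group records whose ITS2 strings are byte-identical.

    When ``annotations`` is given, comparison uses the delimited ITS2
    substring; otherwise the full residues. Groups are sorted by
    descending size, then by the lexicographically smallest member id;
    the number of groups is the haplotype count.
    """
    buckets: dict[str, list[SequenceRecord]] = collections.defaultdict(list)
    for rec in records:
        key = (
            annotations[rec.id].its2_seq(rec) if annotations is not None else rec.residues
        )
        buckets[key].append(rec)
    groups = list(buckets.values())
    for g in groups:
        g.sort(key=lambda r: r.id)
    groups.sort(key=lambda g: (-len(g), g[0].id))
    return groups
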