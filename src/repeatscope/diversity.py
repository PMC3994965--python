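"""Polymorphism summaries: segregating sites, nucleotide diversity, fixed
differences and GC content.

Nucleotide diversity follows the classic definition pi = Pi / L with Pi
the mean number of pairwise nucleotide differences and L the number of
sites compared. Differences are raw mismatches (no multiple-hit
correction) and, under the default complete-deletion policy, any column
containing a gap or an ambiguity code is excluded once for the whole
set before L, S and Pi are computed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Mapping, Sequence

import pandas as pd

from .align import MultipleAlignment
from .seqio import UNAMBIGUOUS, SequenceRecord, SpacerAnnotation

__all__ = [
    "DiversityStats",
    "diversity_stats",
    "fixed_differences",
    "gc_summary",
    "UndefinedStatisticError",
]

GapPolicy = Literal["complete_deletion", "pairwise_deletion"]


class UndefinedStatisticError(ValueError):
    """No comparable sites remain after gap/ambiguity deletion."""


@dataclass(frozen=True)
class DiversityStats:
    """S, Pi (mean pairwise differences), L, pi = Pi/L for one set."""

    S: int
    Pi_upper: float
    L: int
    pi: float
    n: int

    def __post_init__(self) -> None:
        assert 0 <= self.S <= self.L
        assert self.n >= 2


def _clean_columns(rows: Sequence[str]) -> list[int]:
    """Columns where every row carries an unambiguous base."""
    length = len(rows[0])
    return [
        c for c in range(length) if all(r[c] in UNAMBIGUOUS for r in rows)
    ]


def diversity_stats(
    msa: MultipleAlignment,
    gap_policy: GapPolicy = "complete_deletion",
) -> DiversityStats:
    """Segregating sites and nucleotide diversity of an alignment.

    With ``pairwise_deletion`` each pair is compared over its own
    gap-free columns; Pi is then the mean raw difference count, L the
    mean number of compared sites and pi the mean per-pair proportion.
    """
    rows = [msa.rows[k].upper() for k in msa.ids]
    n = len(rows)
    if n < 2:
        raise ValueError("diversity_stats requires at least 2 sequences")
    if gap_policy == "complete_deletion":
        cols = _clean_columns(rows)
        if not cols:
            raise UndefinedStatisticError("no comparable columns remain")
        L = len(cols)
        S = sum(1 for c in cols if len({r[c] for r in rows}) > 1)
        diffs = [
            sum(1 for c in cols if a[c] != b[c])
            for a, b in itertools.combinations(rows, 2)
        ]
        Pi = sum(diffs) / len(diffs)
        return DiversityStats(S=S, Pi_upper=Pi, L=L, pi=Pi / L, n=n)
    if gap_policy != "pairwise_deletion":
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    per_pair = []
    for a, b in itertools.combinations(rows, 2):
        cols = [c for c in range(len(a)) if a[c] in UNAMBIGUOUS and b[c] in UNAMBIGUOUS]
        if not cols:
            raise UndefinedStatisticError("a pair shares no comparable column")
        d = sum(1 for c in cols if a[c] != b[c])
        per_pair.append((d, len(cols)))
    Pi = sum(d for d, _ in per_pair) / len(per_pair)
    L = round(sum(l for _, l in per_pair) / len(per_pair))
    pi = sum(d / l for d, l in per_pair) / len(per_pair)
    all_cols = _clean_columns(rows)
    S = sum(1 for c in all_cols if len({r[c] for r in rows}) > 1)
    return DiversityStats(S=S, Pi_upper=Pi, L=L, pi=pi, n=n)


def fixed_differences(
    group_a: Sequence[str] | Mapping[str, str],
    group_b: Sequence[str] | Mapping[str, str],
) -> int:
    """Columns fixed for one base in A and a different base in B.

    Both groups must come from one joint alignment (equal row lengths);
    columns containing a gap or ambiguity in any row are excluded.
    """
    rows_a = list(group_a.values()) if isinstance(group_a, Mapping) else list(group_a)
    rows_b = list(group_b.values()) if isinstance(group_b, Mapping) else list(group_b)
    if not rows_a or not rows_b:
        raise ValueError("fixed_differences requires two non-empty groups")
    rows_a = [r.upper() for r in rows_a]
    rows_b = [r.upper() for r in rows_b]
    lengths = {len(r) for r in rows_a + rows_b}
    if len(lengths) != 1:
        raise ValueError("groups must share one joint alignment")
    count = 0
    for c in _clean_columns(rows_a + rows_b):
        set_a = {r[c] for r in rows_a}
        set_b = {r[c] for r in rows_b}
        if len(set_a) == 1 and len(set_b) == 1 and set_a != set_b:
            count += 1
    return count


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (as printed tables do)."""
    return float(Decimal(str(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gc_summary(
    records: Sequence[SequenceRecord],
    annotations: Mapping[str, SpacerAnnotation],
) -> pd.DataFrame:
    """Per-record ITS2 GC percentage (1 decimal) with a dataset range.

    The returned frame has columns ``id``, ``its2_length`` and
    ``gc_percent``; the range is available via ``df.attrs['gc_min']``
    and ``df.attrs['gc_max']``.
    """
    data = []
    for rec in records:
        ann = annotations[rec.id]
        data.append(
            {
                "id": rec.id,
                "its2_length": ann.its2_length,
                "gc_percent": _round1(100.0 * ann.gc_fraction),
            }
        )
    df = pd.DataFrame(data)
    if not df.empty:
        df.attrs["gc_min"] = float(df["gc_percent"].min())
        df.attrs["gc_max"] = float(df["gc_percent"].max())
    return df


def type_diversity_table(
    type_msas: Mapping[tuple[str, int], MultipleAlignment],
    unit_lengths: Mapping[tuple[str, int], Sequence[int]] | None = None,
) -> pd.DataFrame:
    """Per-repeat-type diversity report (one row per species x type).

    Keys are (species_label, type_id); values the per-type unit
    alignment. pi is reported at full precision; tables for display can
    round as needed.
    """
    rows = []
    for (label, type_id), msa in type_msas.items():
        stats = diversity_stats(msa)
        rows.append(
            {
                "species": label,
                "type_id": type_id,
                "members": ",".join(msa.ids),
                "n_units": stats.n,
                "S": stats.S,
                "pi": stats.pi,
                "sites_compared": stats.L,
                "unit_lengths": ",".join(
                    str(x) for x in (unit_lengths or {}).get((label, type_id), [])
                ),
            }
        )
    return pd.DataFrame(rows)
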