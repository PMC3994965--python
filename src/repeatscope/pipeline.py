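"""End-to-end orchestration: delimit -> repeats -> diversity -> fold ->
motifs -> screen -> phylo, with a deterministic report bundle.

Stages communicate through documented files (TSV/JSON/FASTA/newick/
dot-bracket) so any of them can be re-run or substituted; identical
config + inputs produce a byte-identical bundle, and every table
records the hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import diversity as div
from . import fold as fold_mod
from . import motifs as motifs_mod
from . import phylo as phylo_mod
from . import repeats as repeats_mod
from . import screen as screen_mod
from . import seqio
from .align import MultipleAlignment, center_star_msa
from .synth import DEFAULT_FLANK3, DEFAULT_FLANK5

logger = logging.getLogger("repeatscope")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and paths of one pipeline run (JSON round-trip)."""

    fasta: str = ""
    outdir: str = "repeatscope_out"
    ref5: str = DEFAULT_FLANK5
    ref3: str = DEFAULT_FLANK3
    min_flank_identity: float = 0.80
    period_range: tuple[int, int] = (80, 130)
    min_copies: int = 3
    typing_threshold: float = 0.80
    nr_band: tuple[float, float] = (0.40, 0.80)
    motif: str = "GGGTGTG"
    motif_max_mismatch: int = 2
    suboptimal_fraction: float = 0.05
    max_structures: int = 25
    run_fold: bool = True
    max_flank_rate: float = 0.05
    min_hairpins: int = 3
    min_stem_pairs: int = 15
    max_internal_loops: int = 3
    bootstrap_reps: int = 200
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        for key in ("period_range", "nr_band"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analytic settings only (paths excluded), so the
        same analysis in a different directory yields the same hash."""
        data = dataclasses.asdict(self)
        data.pop("fasta", None)
        data.pop("outdir", None)
        payload = json.dumps(data, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def validate(self) -> None:
        if not (0.5 <= self.typing_threshold <= 1.0):
            raise ValueError("typing_threshold outside [0.5, 1]")
        if not (0.0 <= self.nr_band[0] < self.nr_band[1] <= 1.0):
            raise ValueError("nr_band must be an increasing sub-interval of [0,1]")
        if self.period_range[0] < 10 or self.period_range[0] >= self.period_range[1]:
            raise ValueError("invalid period_range")
        if not (0.0 <= self.suboptimal_fraction <= 0.2):
            raise ValueError("suboptimal_fraction outside [0, 0.2]")


def _architecture_json(arch: repeats_mod.Architecture) -> dict:
    return {
        "seq_id": arch.seq_id,
        "pattern": arch.pattern(),
        "array_span": list(arch.array_span),
        "array_fraction": round(arch.array_fraction, 4),
        "elements": [
            {
                "label": e.label,
                "type": e.type_id,
                "start": e.start,
                "end": e.end,
                "identity": round(e.identity, 3),
            }
            for e in arch.elements
        ],
    }


def _schematic(arch: repeats_mod.Architecture, its2_length: int, width: int = 78) -> str:
    """One-line text schematic of the element layout (array to scale)."""
    scale = width / its2_length
    line = ["-"] * width
    for e in arch.elements:
        a = int(e.start * scale)
        b = max(a + 1, int(e.end * scale))
        mark = "N" if e.type_id == repeats_mod.NONREPEATED else str(e.type_id)
        for x in range(a, min(b, width)):
            line[x] = mark
    return f"{arch.seq_id:>14} 5'-{''.join(line)}-3' {arch.pattern()}"


def run_pipeline(
    config: PipelineConfig,
    records: Sequence[seqio.SequenceRecord] | None = None,
) -> Path:
    """Run every stage and write the report bundle; returns the outdir.

    Records may be passed directly (e.g. from the generator) instead of
    ``config.fasta``. Per-record failures are logged and skipped; a
    failure summary is always written.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "structures").mkdir(exist_ok=True)
    cfg_hash = config.config_hash()
    (outdir / "config.json").write_text(config.to_json())

    if records is None:
        records = seqio.read_fasta(config.fasta)

    fold_params = fold_mod.FoldParams(suboptimal_fraction=config.suboptimal_fraction)
    thresholds = screen_mod.ScreenThresholds(
        max_flank_rate=config.max_flank_rate,
        min_hairpins=config.min_hairpins,
        min_stem_pairs=config.min_stem_pairs,
        max_internal_loops=config.max_internal_loops,
    )

    annotations: dict[str, seqio.SpacerAnnotation] = {}
    architectures: list[repeats_mod.Architecture] = []
    type_msas: dict[tuple[str, int], MultipleAlignment] = {}
    unit_lengths: dict[tuple[str, int], list[int]] = {}
    motif_rows: list[dict] = []
    verdicts: list[screen_mod.PseudogeneVerdict] = []
    all_units: dict[str, str] = {}
    failures: list[dict] = []

    for rec in records:
        try:
            ann = seqio.delimit_its2(rec, config.ref5, config.ref3,
                                     config.min_flank_identity)
            annotations[rec.id] = ann
            its2 = ann.its2_seq(rec)

            units = repeats_mod.find_tandem_array(
                its2,
                period_range=config.period_range,
                min_copies=config.min_copies,
                motif=config.motif,
                seq_id=rec.id,
            )
            if units:
                typed, types = repeats_mod.assign_types(units, config.typing_threshold)
                arch = repeats_mod.classify_nonrepeated(
                    its2, typed, types, config.nr_band, seq_id=rec.id
                )
                architectures.append(arch)
                by_type: dict[int, list[repeats_mod.RepeatUnit]] = {}
                for e in arch.elements:
                    if isinstance(e.type_id, int):
                        by_type.setdefault(e.type_id, []).append(e)
                for type_id, members in by_type.items():
                    key = (rec.id, type_id)
                    unit_lengths[key] = [len(m) for m in members]
                    if len(members) >= 2:
                        type_msas[key] = center_star_msa(
                            {m.label: m.unit_seq for m in members}
                        )
                    for m in members:
                        all_units[f"{rec.id}/{m.label}.{type_id}"] = m.unit_seq
                hits = motifs_mod.unit_motif_hits(
                    [e.unit_seq for e in arch.elements],
                    config.motif,
                    config.motif_max_mismatch,
                )
                for e, hit in zip(arch.elements, hits):
                    motif_rows.append(
                        {
                            "seq_id": rec.id,
                            "unit_label": e.label,
                            "type": e.type_id,
                            "pattern": hit.pattern if hit else "",
                            "position": hit.position if hit else -1,
                            "mismatches": hit.mismatches if hit else -1,
                            "context": "unit_5prime" if hit else "none",
                        }
                    )

            rate = screen_mod.flank_substitution_rate(rec, ann, config.ref5, config.ref3)
            if config.run_fold:
                structures = fold_mod.suboptimal_structures(
                    its2, fold_params, config.max_structures
                )
                with open(outdir / "structures" / f"{rec.id}.db", "w") as fh:
                    for s in structures:
                        fh.write(f"{s.dot_bracket} {s.score}\n")
                verdicts.append(
                    screen_mod.assess_functionality(rec.id, structures, rate, thresholds)
                )
        except Exception as exc:  # per-record isolation
            logger.warning("record %s failed: %s", rec.id, exc)
            failures.append({"id": rec.id, "error": str(exc)})

    header = f"# config_hash={cfg_hash}\n"

    ann_df = pd.DataFrame(
        [
            {
                "id": rid,
                "its2_start": a.its2.start,
                "its2_end": a.its2.end,
                "its2_length": a.its2_length,
                "gc_fraction": round(a.gc_fraction, 4),
            }
            for rid, a in annotations.items()
        ]
    )
    _write_tsv(ann_df, outdir / "annotations.tsv", header)

    labels = {rec.id: (rec.label or rec.id) for rec in records}
    table2 = div.type_diversity_table(
        {(labels.get(rid, rid) + "|" + rid, t): m for (rid, t), m in type_msas.items()},
        {(labels.get(rid, rid) + "|" + rid, t): v for (rid, t), v in unit_lengths.items()},
    )
    _write_tsv(table2, outdir / "repeat_types.tsv", header)

    (outdir / "architectures.json").write_text(
        json.dumps(
            {"config_hash": cfg_hash,
             "architectures": [_architecture_json(a) for a in architectures]},
            indent=1,
        )
    )
    with open(outdir / "schematic.txt", "w") as fh:
        fh.write(header)
        for arch in architectures:
            fh.write(_schematic(arch, annotations[arch.seq_id].its2_length) + "\n")

    _write_tsv(pd.DataFrame(motif_rows), outdir / "motifs.tsv", header)
    _write_tsv(
        pd.DataFrame([dataclasses.asdict(v) for v in verdicts]),
        outdir / "verdicts.tsv",
        header,
    )

    if len(all_units) >= 4:
        msa = center_star_msa(all_units) if len(all_units) <= 20 else None
        if msa is not None:
            tree = phylo_mod.nj_tree(
                msa=msa, bootstrap_reps=config.bootstrap_reps, seed=config.seed
            )
            (outdir / "repeats.nwk").write_text(tree.newick + "\n")

    (outdir / "run_log.json").write_text(
        json.dumps(
            {
                "config_hash": cfg_hash,
                "seed": config.seed,
                "n_records": len(records),
                "n_delimited": len(annotations),
                "n_architectures": len(architectures),
                "failures": failures,
            },
            indent=1,
        )
    )
    return outdir


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False)
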