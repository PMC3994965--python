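# repeatscope

Analysis of exceptionally large rDNA internal transcribed spacers
(ITS2) whose size is driven by internal tandem repeats — as in the
*Anopheles barbirostris* group, where the ITS2 exceeds 1.5 kb because
its central 55–61% is an array of ~110 bp repeat units. The package is
aimed at molecular entomologists and rDNA evolution researchers who
need to go from spacer amplicon sequences to a quantitative account of
repeat architecture, diversity, secondary structure and functionality.

## What it computes

- **Spacer delimitation.** The ITS2 interval is located between the
  retained 5.8S terminus and 28S start by local alignment against
  reference flank segments; identical spacers collapse to haplotypes.
- **Tandem-repeat architecture.** A seed-and-extend detector (k-mer
  offset voting → wraparound Smith–Waterman against a circular
  consensus → motif-phased unit segmentation → consensus-probe tiling)
  finds the array, segments it into units labelled A, B, C, … from the
  5′ end, clusters them into similarity **types** by single linkage at
  ≥ 0.80 identity, and recognizes degenerate **non-repeated (NR)
  elements** whose identity to a type consensus falls in [0.40, 0.80).
- **Nucleotide diversity.** For each repeat type, segregating sites
  *S* and nucleotide diversity π = Π/*L*, where Π is the mean number
  of pairwise differences and *L* the number of sites compared
  (complete deletion of gap/ambiguity columns, raw mismatch counts).
- **Secondary structure.** A weighted base-pair maximization model
  (G·C = 3, A·U = 2, G·U = 1, +1 per stacked pair) folds the spacer at
  and near its optimum (best-first enumeration of all structures
  within 5% of the optimal score, capped at 25) and extracts hairpins
  (stem–loops) with their internal-loop counts. The conserved unit
  motif `GGGTGTG` (and ≤ 2-mismatch variants) is located at unit 5′
  ends and hairpin stem bases, with a reverse-complement partner check
  on the opposite strand.
- **Pseudogene screen.** A spacer is called *functional* iff (1) its
  ~90 nt of retained coding flanks show ≤ 5% substitutions against the
  reference and (2) every near-optimal structure contains ≥ 3 long
  hairpins (stem ≥ 15 pairs, ≤ 3 internal loops).
- **Repeat phylogeny.** Units from several species are aligned
  (center-star), p-distances computed with pairwise deletion, a
  neighbor-joining tree built with column-bootstrap supports, and
  monophyly of homologous types across species tested via edge
  bipartitions — the topological signature of repeat duplication
  predating speciation.
- **Synthetic families.** A generator plants all of the above —
  interleaved unit types, 5′ motifs, inverted-repeat stems, 3′-biased
  indels, decayed NR copies, conserved flanks — with full ground truth,
  so every stage is testable without any sequence download.

## Worked example

```python
import dataclasses
from repeatscope import *
from repeatscope.synth import species_presets, generate_family
from repeatscope.diversity import diversity_stats
from repeatscope.align import center_star_msa

spec = dataclasses.replace(species_presets()["clade_i"], seed=17)
rec, truth = generate_family(spec)          # 1.6 kb amplicon + truth
ann = delimit_its2(rec, spec.flank5, spec.flank3)
its2 = ann.its2_seq(rec)
units = find_tandem_array(its2, seq_id=rec.id)
typed, types = assign_types(units)
arch = classify_nonrepeated(its2, typed, types, seq_id=rec.id)
```

Printed summary of that run:

```
ITS2: 45..1590 (1545 bp, GC 59.2%)
architecture: 12121212  array fraction 0.57
type 1: units A,C,E,G  S=2  pi=0.01  sites=112
type 2: units B,D,F,H  S=2  pi=0.01  sites=108
hairpins per structure: 7-7 across 25 structures
flank substitution rate: 0.000  verdict: functional
```

Reading: the 1,545 bp spacer carries eight ~110 bp repeats in two
alternating similarity types (`12121212`) occupying 57% of its length;
within-type diversity is low (π = 0.01 over 112/108 compared sites,
2 segregating sites each); every near-optimal secondary structure
folds the repeats into seven long hairpins; and clean coding flanks
plus robust hairpin formation clear the pseudogene screen.

The same pipeline runs from the shell:

```bash
repeatscope simulate --preset clade_i --seed 17 --out sim/
repeatscope run --fasta sim/cohort.fasta --out out/
```

writing `annotations.tsv`, `repeat_types.tsv`, `architectures.json`, a
text schematic of each element layout, per-structure dot-bracket
files, motif and screen verdict tables, and `repeats.nwk`. Deposited
spacer sequences can be analysed the same way by pointing `--fasta`
(or `repeatscope delimit --ref5/--ref3` with real 5.8S/28S flank
references) at local FASTA/GenBank files; no network access is used.

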