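# Methods

This note documents the models and procedures implemented in
`repeatscope`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Spacer delimitation

The ITS2 is delimited as the interval strictly between local-alignment
hits of two user-supplied reference segments: the 3′ terminus of 5.8S
and the 5′ start of 28S (≥ 20 bp each; the bundled defaults are 45 + 45
nt synthetic stand-ins used by the test suite, not real gene termini).
Local alignment (match +1, mismatch −1, gap −2) rather than exact
search is used because amplicons retain ~90 coding nucleotides that can
carry occasional substitutions. A hit must reach the identity floor
(default 0.80) **and** cover ≥ 60% of the reference — without the
coverage requirement a chance 8–10 bp perfect match would satisfy the
identity test. Bases the local alignment trims at the reference ends
are extrapolated so the flank interval always maps the full reference.
Coordinates are 0-based, half-open throughout; a printed length is
always `end − start`. GC content is computed over unambiguous bases
only (ambiguity codes leave both numerator and denominator).

## Pairwise and multiple alignment

Global alignment uses affine gap scoring (match +1, mismatch −1, gap
open −2, extend −1) with terminal gaps at the 3′ (right) end free,
because the unit-length variation seen within repeat types comes from
indels clustered at unit 3′ ends. Pairwise alignment is delegated to
Biopython's `PairwiseAligner`; co-optimal paths resolve to the
aligner's canonical traceback order, so results are deterministic.
Multiple alignment of unit sets (2–20 short, highly similar sequences)
is center-star: the center maximizes summed pairwise identity, other
sequences merge by "once a gap, always a gap", and an existing gap
column is reused when a later sequence needs a gap at the same
position. For inputs of this kind center-star is near-optimal and
entirely reproducible, which matters more here than the marginal gains
of a progressive aligner.

## Tandem-array detection

The detector is deliberately transparent and parameterized, so it can
be validated against planted truth:

1. **Period voting.** Exact k-mer self-matches (k = 13; k-mers with
   more than 30 occurrences are skipped) vote for their offset.
   Offsets up to 3.5× the maximum unit length are collected because,
   with two or three interleaved similarity types, units adjacent in
   sequence belong to different types and the *fundamental tandem
   period is a di- or trimer of units*. Offset votes are clustered
   (±5 bp), and up to three candidate periods are kept, ordered
   shortest-first since longer periods are often harmonics.
2. **Wraparound tiling.** For each candidate, a provisional cycle is
   read directly from the middle of the k-mer support span and the
   spacer is aligned against it circularly (Smith–Waterman with wrap
   from the last consensus column to the first; match +2, mismatch −2,
   gap −4). Disjoint array segments — e.g. arrays interrupted by
   decayed elements — are recovered by masking each traced path and
   re-running, up to 8 passes.
3. **Consensus refinement and phasing.** A refined cycle consensus is
   the column majority over *interior* copies only (both boundaries at
   wrap points, length within 10% of the period); partial edge copies
   carry a different phase and would corrupt the majority. Ties keep
   the first copy's base, so a 2-copy consensus is never scrambled.
   The consensus is rotated so the best GGGTGTG-like hit sits at
   position 0, then cut into unit sub-consensi at interior motif hits;
   the cut set is chosen by dynamic programming so that every segment
   length stays within a tolerant unit band (0.7×min to 1.3×max of
   `period_range`), minimizing total motif mismatches — this stops
   chance 2-mismatch hits from over-splitting units. If no
   motif-consistent partition exists, the consensus is divided evenly.
4. **Profile tiling and polish.** The spacer is tiled with local-
   alignment matches of each sub-consensus (iterated with masking;
   hits must cover ≥ 75% of the probe), non-overlapping hits are
   selected greedily by identity, and small inter-unit gaps (diverged
   3′ tails the local alignment trimmed) are absorbed into the
   upstream unit. Candidates are scored by the summed identity margin
   above the detection floor (0.60), which rewards both copy number
   and copy fidelity without letting near-threshold decayed segments
   outvote genuine units; a longer period must beat a shorter one by
   5% to win. The winner's units are then clustered and re-tiled with
   per-type consensi (two rounds), and finally uncovered segments in
   and just 3′ of the array are compared *against each other* — a
   similarity class whose members all fell between probes (possible
   when the cycle consensus came out chimeric) is recovered from its
   internal similarity (mutual identity ≥ 0.80 over ≥ 0.75 of a
   median unit).

On planted families in the design regime (unit length 95–120 bp, 5–9
copies, 1–2 types, within-type diversity ≤ 0.08, occasional 3′ indels)
the detector recovers ≥ 95% of units within 5 bp and always finds the
correct number of types; the acceptance script recomputes this.

## Typing and non-repeated elements

Units cluster by single linkage at a typing identity ≥ 0.80. The
typing identity is **matches over the shorter sequence length**: a
3′-end deletion then does not count against membership (within-type
diversity runs up to ~0.14, so base identity stays ≥ ~0.86), while the
measure cannot be inflated the way a gap-column-excluded identity can —
unrelated 110-mers aligned gappily retain mostly matching columns and
would otherwise cross the threshold. Types are numbered by the
position of their 5′-most member; only multi-member clusters become
types. The per-type consensus is the column majority of the members'
center-star alignment.

Degenerate (non-repeated, NR) elements are detected two ways: an
untyped unit whose identity to a type consensus falls in the NR band
(default [0.40, 0.80)) is reclassified, and uncovered stretches inside
the array or on its 3′ side are scanned with anchored, effectively
ungapped (Hamming-style) comparisons against the type consensi (±5 bp
anchor offsets). The ungapped measure is essential: under permissive
gap scoring, unrelated sequence reaches ~0.45–0.55 identity and the
band floor of 0.40 would misfire, whereas positional similarity of
random sequence sits near 0.27. NR calls 5′ of the first intact unit
are rejected — decayed copies arise within or at the 3′ end of the
array. Architecture elements (typed units + NR) are relabelled
A, B, C, … in positional order, so type membership tables list letters
with NR positions skipped.

## Diversity

`diversity_stats` implements π = Π/*L*: Π is the mean count of raw
pairwise differences (no multiple-hit correction) and *L* the number
of compared sites. The default complete-deletion policy removes any
column containing a gap or ambiguity once for the whole set — matching
the convention of reporting a single "sites compared" value per unit
set — and *S* counts columns with ≥ 2 distinct bases among the
remaining columns. A pairwise-deletion policy is available; under it π
is the mean per-pair proportion and *L* the mean per-pair site count.
Fixed differences between two groups sharing one joint alignment count
columns where each group is internally invariant and the two differ,
excluding gap/ambiguity columns. Everything here is verified against
brute-force double-loop counting in the tests and acceptance script.

## Folding model

Folding is a weighted Nussinov dynamic program: each pair contributes
G·C = 3, A·U = 2, G·U = 1, plus a +1 bonus for each pair stacked
directly on another; hairpin loops need ≥ 3 unpaired bases;
pseudoknots are disallowed. This is *not* a thermodynamic model — its
score is not a free energy, has no temperature dependence, and no
printed energy value is comparable with it. The claims built on it are
deliberately confined to hairpin *presence and robustness*, which a
base-pair maximization model captures. Two matrices are filled (best
score of an interval; best score given its ends pair), in a compiled
kernel; the traceback prefers pairing the interval ends, then
bifurcation at the smallest split point, making the reported optimum
structure deterministic.

Near-optimal structures ("5% suboptimal folding") are enumerated
best-first over an exclusive decomposition of the DP — each structure
is generated exactly once with its exact score — down to
(1 − f) × optimum (f = 0.05) and capped at 25 structures. Two
implementation points keep this tractable at 1.5 kb: multi-way split
choices expand lazily (the best split is taken and the flanking
sub-ranges re-queued with exact bounds), and score ties pop
newest-first so the search drives one structure to completion instead
of wandering across a tie plateau. On sequences ≤ 12 nt the output is
byte-for-byte the exhaustively enumerated structure list.

Hairpins are maximal stem–loops: from each terminal loop, pairs are
walked outward until a multiloop or the exterior; unpaired
interruptions count as internal loops; stems need ≥ 4 pairs by default.

## Motifs

`scan_motif` reports every window within Hamming distance 2 of
GGGTGTG (the budget covers all observed field variants: GGGTGGT,
GGGTGGG, GGGTGCG, TGGTGTG). "At the 5′ end of most units" is
operationalized as a hit starting within the first 10 nt of more than
50% of typed units; the full per-unit table is always emitted so
stricter readings can be applied downstream. The stem-base check
searches a 10 nt window at the hairpin's 5′ base strand for a motif
hit and tests whether the 3′ base strand window contains its reverse
complement, with G·U counted as complementary in RNA context.

## Pseudogene screen

Two criteria, both required for a *functional* call:

1. **Flank conservation** — substitutions per site pooled over both
   retained coding flanks (global alignment to the references, gap
   columns excluded) ≤ 0.05. The threshold is this package's
   operationalization of "low substitution rate"; it is configurable.
2. **Hairpin robustness** — every structure in the near-optimal set
   contains ≥ 3 *qualifying* hairpins, where qualifying means a stem
   of ≥ 15 pairs with ≤ 3 internal loops.

The qualifying-hairpin definition was calibrated once on the
generator before the tests were frozen: under the base-pair
maximization model random 1.5 kb sequence still pairs heavily, so a
bare hairpin count cannot separate repeat arrays from background, but
long clean stems can — across 25 near-optimal structures, random
spacers contain 0–1 qualifying hairpins while all five species-like
presets contain ≥ 3 (their units carry ~20 bp planted inverted
repeats). Verdicts are pure functions of (rate, structure set,
thresholds).

## Repeat phylogeny

Unit sets from multiple species are aligned together (center-star),
p-distances computed with pairwise deletion of gap/ambiguity columns,
and a neighbor-joining tree built (scikit-bio's NJ; negative branch
lengths clamped to zero). Supports come from resampling alignment
columns with replacement (default 500 replicates, seeded) and counting
bipartition recurrence. Trees are unrooted; monophyly of a leaf subset
means some edge bipartition separates exactly that subset (singletons,
the full set, and complements of singletons are trivially
monophyletic). A Bayesian analysis would estimate posterior clade
probabilities instead; the claim tested here — homologous repeat types
cluster across species when duplication predates speciation — is
topological, and NJ with bootstrap is sufficient and fully
reproducible for it.

## Synthetic data generator

`generate_family` emulates the observed spacer anatomy: a spacer of
target length (presets 1,519–1,730 bp) whose central 50–65% is a
contiguous run of elements laid out by an explicit architecture
pattern (e.g. `12121212`, `1212121N`, `1NN1212N`); one random ancestral
unit per type carrying the 7-mer motif at its 5′ end and a planted
20 bp inverted repeat (arm = motif + filler, loop 5 nt), so each unit
folds into a long hairpin whose 5′ base strand starts with the motif;
per-unit point substitutions (transition:transversion 2:1) at *half*
the specified `per_site_divergence`, making that parameter the
**expected within-type pairwise diversity** and directly comparable to
recovered π; optional single ≤ 6 bp indels confined to the final 15 bp
of a unit; NR elements as decayed copies of the neighbouring type's
ancestor, mutated to a target identity drawn from [0.45, 0.75]; random
non-repetitive filler splitting the remaining length around the array;
and fixed 45 + 45 nt coding flanks. Everything is driven by one seed
and is byte-reproducible. `generate_speciation_cohort` draws the type
ancestors once (duplication in the common ancestor), applies
species-level substitutions to each species' inherited ancestors, and
then generates per-species families — planting the homologous-type
monophyly signal.

Species presets encode the per-species summaries (spacer length, unit
counts and lengths, type memberships, within-type diversity, NR
counts). The placement of the unknown-species preset's two interior
degenerate elements (letters B and C) is a modelling choice forced by
its typed members being A, D, F and E, G.

What the generator does **not** emulate: replication slippage as a
process (copy numbers are fixed by the pattern, not evolved),
inter-element spacers, intra-individual variation among rDNA copies,
PCR/sequencing error, coalescent structure across specimens, and any
base-composition heterogeneity beyond a uniform GC target. Passing
tests therefore demonstrate correct recovery of planted structure
under a realistic noise model, not performance on chromatogram-level
artifacts or on repeat families whose types are themselves ancient
paralogs of each other.

## Problem sizes and runtime choices

The bundled verification runs use sizes that keep the full suite and
the acceptance script within a few minutes on one CPU: 200 planted
families for recovery (100 in the script), 100 seeds for the
diversity emulation (50 in the script), 25 near-optimal structures
per fold, 1,000/500-case oracle batteries for counting and folding
(300/200 in the script), and 100–200 bootstrap replicates where trees
are built. These sizes were chosen so that Monte-Carlo standard errors
are well inside the asserted bands.

## Known limitations

- The folding score is ordinal, not thermodynamic; absolute energies
  and temperature effects are out of scope by design.
- Detection assumes units of 80–130 bp in a single central array with
  at least two mutually recognizable copies per type; dispersed
  repeats, nested periodicities outside the 1–3.5 unit window, or
  types whose members have decayed below ~0.8 mutual identity are not
  recovered as types (the decayed copies surface as NR elements).
- Center-star alignment is capped at 20 sequences; the pipeline skips
  the repeat tree for larger unit sets rather than degrade quality.
- Boundary precision at unit 3′ ends is limited by real ambiguity:
  with 3′-clustered indels and ≥ 8% divergence, a few boundaries land
  5–15 bp off, which is why recovery is scored with a 5 bp tolerance
  and a 95% bar rather than exactness.
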