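# Methods

## Scope and data flow

The package implements the computational workflow of a phosphorylated
HLA-II ligandome study downstream of the MS search engine. Its input is
an identification table in the MaxQuant `msms.txt` dialect (one PSM per
row with an Andromeda-style identification score, the delta score to the
second-best match, and per-site phospho localization probabilities),
together with a per-sample HLA-II typing manifest, a proteome in FASTA
and a phosphosite catalogue. Running the search engine itself, FDR
estimation, protein inference and spectral processing are out of scope.

Stages: (1) parse and quality-filter PSMs; (2) assign each
phosphopeptide to the alleles of its sample with a PWM predictor and a
%rank cutoff; (3) build and compare binding motifs; (4) positional and
kinase-motif statistics of phosphosites; (5) a leave-one-sample-out
benchmark of the phospho-aware predictor.

## PSM filtering

A PSM is kept iff identification score ≥ 40, delta score ≥ 10, **every**
phospho localization probability strictly > 0.75, and peptide length in
[12, 25]. The localization boundary is strict, the others inclusive; the
filter is a pure, idempotent, order-preserving subsequence operation.
Rows with unparseable modification syntax are excluded with a warning
and an exclusion counter, never silently. Non-phospho variable
modifications (Met oxidation, N-terminal acetylation) are parsed and
ignored: phosphorylation is the object of study. Peptides with equal
sequence but different phosphosite placements are distinct objects.

## The predictor

One model per allele: a 9 × 23 PWM (20 amino acids + pS/pT/pY, written
as lowercase `s t y` in modified sequences) with background-proportional
pseudocounts (default weight 5), a 23-letter background, and a per-length
%rank calibration. This is deliberately a *single-PWM max-over-offsets
log-odds scorer* — the minimal model that supports core prediction,
motif construction and %rank thresholds. Offset priors, flanking-region
terms and multiple binding specificities per allele are extension
points, not implemented.

* **Background.** Canonical frequencies from the supplied proteome (or a
  fixed human-proteome table); each phospho symbol gets its parent's
  frequency × a phospho prior (default 0.01), then the 23-vector is
  renormalized. Phospho background frequencies are not measurable from
  an unmodified proteome, so this choice is explicit and configurable.
* **Scoring.** Sum of log2(PWM/background) over the 9 core positions,
  maximized over all offsets; ties break to the smallest offset. Scores
  are unitless bits.
* **%rank.** For each length 12–25, `n_per_length` random proteome
  windows (default 10,000, seeded) are scored and sorted;
  `%rank = 100 · (1 + #{calibration ≥ score}) / (N + 1)`, so the best
  achievable rank is 100/(N+1) and the function is antitone in the
  score. Calibration is per length because length-correction of the
  reference ranks is otherwise unspecified; this is documented behaviour.
* **Training cores for S vs pS** are counted independently — no
  statistical strength is shared between a residue and its
  phosphorylated form.

Models serialize to a versioned plain-text format (header, 9 × 23
frequency block, calibration block).

## Assignment

Each filtered peptide is scored against every allele of its sample;
alleles with %rank ≤ 10 (inclusive boundary, declared and tested) are
kept, sorted by rank. The default discovery mode substitutes phospho
residues with glutamate before scoring — phosphate and glutamate share a
negatively charged side chain, and discovery predates a phospho-aware
model — while the benchmark retrains and scores natively on the
23-letter alphabet. Peptides found in several samples are assigned per
sample; the unique-ligand set is keyed by (sequence, phosphosite set).
Peptides passing for several alleles of one sample contribute one
interaction each (a `best_only` switch restricts motif membership to the
top-ranked allele). QC compares identification-score distributions of
assigned vs unassigned phosphopeptides with two-sample
Kolmogorov–Smirnov tests; a random control draws phosphosite-pool
peptides with the observed ligand length distribution and reports their
(higher) exclusion rate.

## Motifs

Display motifs are pure observed frequencies (zero pseudocount), unlike
the pseudocounted predictor PWMs. The phospho motif of an allele uses
only cores carrying a phosphosite within P1–P9. For distances, the
phospho motif's phospho rows are dropped and each position renormalized;
the unmodified side is not renormalized (it carries no phospho mass by
construction). Distance is the Euclidean norm over the 9 × 20 cells.
Intra-allele distances (phospho vs own unmodified motif, n values) are
compared with inter-allele distances (vs all other alleles' unmodified
motifs, n·(n−1) values) by a one-sided Wilcoxon rank-sum test. Alleles
with fewer than 10 in-core phosphopeptides are reported but excluded
from the test as unstable. Motif matrices export as TSV consumable by
logo tools, with phospho symbols flagged for distinct coloring;
rendering itself is out of scope.

## Positional statistics

Coordinates are 0-based half-open internally; user-facing output uses
1-based P1–P9. A phosphosite is core if it lies in
[core_offset, core_offset+9), terminal-N if its index is < 3,
terminal-C if ≥ length−3 (a peptide with both contributes to both;
site- and peptide-level counts are both reported because the published
convention is ambiguous). The P1–P9 distribution uses all peptides with
at least one in-core phosphosite; each in-core site of a
multiply-phosphorylated peptide counts once, making the per-position
denominator well defined, and frequencies sum to 1.

## Kinase motifs

Patterns use a bracket grammar (`[pS/pT]P`, `RXX[pS/pT]`, wildcard `X`)
with exactly one phospho anchor. Ligands are N- and C-terminally
extended from their source protein (flank = longest motif − 1; the
lexicographically smallest matching protein id wins; termini pad with a
sentinel that matches no motif position, wildcard included — a window
running into padding is no match but stays in the denominator). The
denominator of a motif is the number of sites matching its anchor set:
phosphosites of the anchor's parent residues in the phospho stratum and
on the phosphoproteome catalogue, unmodified parent residues in the
unmodified stratum (where phospho tokens stand for their parents). A
plain residue token matches only the unmodified residue. Enrichment of
phospho vs unmodified ligands is a one-sided Fisher's exact test on
[count, denom−count] × 2; results sort by phosphoproteome frequency.
"Non-redundant" selection drops a motif whose phospho-stratum match set
is contained in a shorter retained motif's match set (configurable off;
no published rule exists, so the rule is declared and testable). The
source-gene bias control partitions a gene universe by membership in the
ligand-source and motif-bearing sets and reports the odds ratio
(a·d)/(b·c), Haldane-corrected (+0.5, flagged) iff a cell is zero.

## Benchmark

Leave-one-sample-out: every phosphopeptide found in the held-out sample
is removed from training in all its occurrences (asserted on every
fold), per-allele models are retrained per arm — native 23-letter cores
for `native23`, glutamate-substituted cores for `substitute_E` — and the
held-out positives plus five-fold negatives are scored; a peptide's
score against a multi-allele sample is its minimum %rank over the
sample's alleles. Negatives are drawn once per fold (seed = base + fold
index) and shared across arms: a catalogue phosphosite, a length in
12–25 and the site's position within the peptide are chosen uniformly
and the source protein sliced, rejecting out-of-bounds draws and
duplicates of positives. AUC is the Mann–Whitney probability with ties
counted 1/2 (midranks — the tie convention is chosen and tested); MCC
and F1 classify binders at %rank ≤ 5, with MCC reported as flagged zero
when a confusion-matrix marginal vanishes. Arms are compared with a
paired two-sided Wilcoxon signed-rank test, zero differences dropped
(all-zero: p = 1, flagged). The external-validation mode is the same
harness pointed at an unseen peptide set, unfiltered by any predictor.

## The synthetic-data generator

The generator emits every input — proteome, identification tables,
manifests, phosphosite catalogue — from planted per-allele motifs, plus
a ground-truth ledger (true allele, core offset, phosphosites per
peptide). Defaults are the study conditions; all randomness flows from
one seed and outputs are byte-reproducible.

* **Alleles and samples.** 6 alleles with distinct anchor preferences at
  P1/P4/P6/P9 (0.85 of the column mass on two favoured residues), one
  monoallelic sample each plus 4 three-allele samples — a desk-scale
  version of a mixed mono-/polyallelic cohort.
* **Ligands.** Lengths 12 + Binomial(13, 3/13), peaking at 15-mers.
  Cores are drawn from the planted PWM *subject to presentation
  selection*: a core must score above the 99th percentile of background
  9-mers under its own PWM, because MS observes presented peptides, and
  presented ligands are top-percentile binders. 120 unmodified and 80
  phospho PSMs per sample.
* **Phosphosites.** Multiplicity (85.4, 13.3, 1.3)% mono/di/tri; a site
  falls in the core with probability 0.6, placed over P1–P9 with weights
  peaking at P5 and depleted at P1, else in a terminal flank (C:N =
  63:37; N-terminal positions weighted (24, 30.5, 45.5)%). Phospho
  residues are S/T/Y = (80, 15, 5)%. Binding selection acts on the
  phosphorylated form, with the phosphate treated as glutamate-like in
  the groove: placements whose phosphate would abolish binding (e.g. on
  an anchor whose pocket wants an aromatic) are resampled. This, not a
  hand-set rule, produces the positional specificity — P1 depletion and
  anchor avoidance — in the emitted repertoire. A `phospho_anchor_position`
  mode instead plants a pocket that *prefers* the phosphate (mass on
  pS/pT at one anchor), the regime in which the native 23-letter
  predictor must beat the substitution arm.
* **Kinase signature.** The residue after a ligand phosphosite is
  proline with probability 7.44%; catalogue sites are selected so 32% of
  the non-ligand entries are proline-followed — a proline-directed
  signature strong in the phosphoproteome and weak in presented ligands.
* **Contaminants and noise.** 48% of phospho PSMs are random proteome
  slices (disjoint from ligand regions) carrying one phosphosite, with
  identification scores from lower distributions (score N(85,25) vs
  N(120,20); delta N(18,10) vs N(45,15), truncated at 0); 8% of sites
  get a localization probability below 0.75; a few short (8–11-mer)
  contaminants exercise the length filter. `SynthConfig.noiseless()`
  defines the no-contaminant, no-sub-threshold-noise condition under
  which the pipeline is expected to recover ≥ 95% of planted
  interactions.
* **Proteome.** 500 proteins, geometric lengths (mean 450, min 60),
  human-like amino-acid composition; ligand parents are embedded
  left-to-right with one-residue gaps, so every emitted peptide is an
  exact proteome substring.

**What the generator does not emulate:** spectral noise and search-engine
behaviour beyond its output table; shared peptides between samples;
inter-allele motif correlation (real HLA-II motifs are more redundant);
realistic gene-level structure of the phosphoproteome; length-dependent
binding preferences. Passing recovery tests therefore demonstrates the
pipeline's internal consistency on motif-bearing data, not performance
on real spectra.

## Numerical choices and degenerate inputs

Log base 2 throughout; PWM rows validated to sum to 1 within 1e-9; ties
in core scoring break to the smallest offset; %rank of an
above-maximum score is 100/(N+1), never 0. Degenerate cases are explicit:
empty motif after in-core restriction → flagged `None`; a PWM position
with all mass on phospho symbols cannot be renormalized (error); a
rank-sum test on all-equal distances and an all-tied paired test return
flagged p-values instead of numbers that look meaningful. Fisher
p-values come from the exact hypergeometric tail (verified against
enumeration for all 2×2 tables with n ≤ 30).

## Problem sizes in the test suite

The suite runs desk-scale: worlds of 10 samples (~2000 PSMs, ~225k
proteome residues), calibration 200–2000 peptides per length, LOSO with
500-peptide calibrations. PWM column recovery is demonstrated at 2000
sampled cores: the counting estimator is exact, and at a few hundred
draws the sampling noise of near-background columns alone caps the
per-position Pearson correlation below the 0.95 target, so the larger
draw isolates the property being tested from that noise floor.

## Known limitations

The scorer is a single PWM per allele: no flanking-region energy, no
offset prior, no per-length binding preference, and DQ/DP α/β pairing is
not modelled beyond treating each listed allele name as one model. The
%rank reference is the unmodified proteome; presented-peptide priors are
absent. Real phosphopeptidome effect sizes (e.g. kinase-motif
enrichment) are small, and this package's statistics will be
underpowered at desk scale — the generator's planted effects are
detectable by design, real ones need cohort-scale data.
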