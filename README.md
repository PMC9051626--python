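# phlaii

Analysis of **phosphorylated HLA class II ligands** from immunopeptidomics
data: PSM-level quality filtering of MS identification tables, per-allele
binding prediction with position weight matrices over a 23-letter
(phospho-aware) amino-acid alphabet, allele assignment of phosphopeptides,
phospho binding-motif construction and comparison, positional and
kinase-motif statistics, and a leave-one-sample-out predictor benchmark.
A synthetic-data generator with complete ground truth makes every stage
testable end to end.

## Who this is for

Immunopeptidomics groups asking how phosphorylated peptides are presented
on HLA-II molecules: which alleles present them, where the phosphosite
sits relative to the 9-mer binding core (P1–P9) and the peptide flanking
regions (PFRs), whether kinase substrate motifs such as `[pS/pT]P` are
enriched among presented phosphopeptides, and how much a phospho-aware
predictor improves over treating phosphoresidues as glutamate.

## The model

Each HLA-II allele is described by a 9-position PWM over the alphabet
`ACDEFGHIKLMNPQRSTVWY` + `pS pT pY`, trained from aligned binding cores
with background-proportional pseudocounts:

    f(a, p) = (count(a, p) + w · b(a)) / (n + w)

A peptide of length 12–25 is scored by the best core over all offsets,

    S(peptide) = max_o Σ_{p=1..9} log2( f(peptide[o+p], p) / b(peptide[o+p]) ),

and the raw score is converted to a **%rank** — its percentile among
random proteome peptides of the same length (lower is better). Allelic
restriction uses %rank ≤ 10; binder classification in the benchmark uses
%rank ≤ 5. Phospho background frequencies cannot be measured from an
unmodified proteome, so each phospho symbol receives its parent residue's
frequency times a configurable prior (default 0.01).

Two scoring modes mirror the two phases of a phosphopeptidome study:
`substitute_E` replaces phosphoresidues with glutamate before scoring
(discovery with a phospho-blind predictor; phosphate and glutamate share
a negatively charged side chain), and `native23` scores the 23-letter
sequence directly (the retrained, phospho-aware predictor).

## Worked example

```python
from phlaii.synth import SynthConfig, generate_world
from phlaii import pipeline
from phlaii.assignment import summarize_peptidome, qc_score_separation

world = generate_world(SynthConfig(seed=1))          # proteome, PSMs, manifests, truth
models = pipeline.discovery_models_from_world(world, calibration_n=2000, seed=2)
res = pipeline.run_discovery(world.psms, world.manifests, models)

phos = [x for x in res.outcome.interactions if x.peptide.n_phospho]
s = summarize_peptidome(phos)
print(len(res.filtered), s.n_interactions, s.n_unique_peptides, s.n_alleles)
```

prints `1823 431 399 6`: of 2000 synthetic PSMs, 1823 pass the quality
filters (identification score ≥ 40, delta score ≥ 10, localization
probability > 0.75, length 12–25); the phosphopeptides among them yield
431 peptide–allele interactions at %rank ≤ 10, i.e. 399 unique
phospho-ligands across 6 alleles. The 37.1% of phosphopeptides assigned
to no allele are contaminant-like, which the QC confirms:

```python
pa = [r for r in res.outcome.assigned_psms if r.peptide.n_phospho]
pu = [r for r in res.outcome.unassigned_psms if r.peptide.n_phospho]
print(qc_score_separation(pa, pu)["peptide_score"])
# KSResult(statistic=0.473, p_value=1.9e-30)  — unassigned scores are lower
```

A single interaction row reads, e.g.,

    mono_01  DRB1_SYN_01  EQNIYVSDNsYsVSV  core YVSDNsYsV  offset 5  %rank 4.20

a 15-mer with phospho-serines (lowercase) at positions 10 and 12, seated
with its core at offset 5 and well inside the 10% rank cutoff.

The same pipeline is available from the shell:

```sh
phlaii synth --seed 5 --out world/
phlaii filter-psms --msms world/msms.tsv --out filtered.tsv
phlaii train --cores cores.tsv --proteome world/proteome.fasta --out models/
phlaii assign --peptides filtered.tsv --manifest world/manifest.tsv --models models/ --out interactions.tsv
phlaii motifs --interactions interactions.tsv --out motifs/
phlaii stats  --interactions interactions.tsv --proteome world/proteome.fasta \
              --motifs kinase.txt --phosphoproteome world/phosphosites.tsv --out stats/
phlaii benchmark --interactions interactions.tsv --manifest world/manifest.tsv \
              --catalogue world/phosphosites.tsv --proteome world/proteome.fasta --out bench/
```

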