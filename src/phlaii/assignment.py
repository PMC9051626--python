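"""Allelic restriction of filtered phosphopeptides.

Each peptide is scored against every HLA-II allele of its sample; alleles
passing the %rank cutoff (default 10%, inclusive) are kept.  Peptides that
pass for no allele are treated as likely co-eluted contaminants or wrong
identifications and excluded from downstream analyses; the Kolmogorov-
Smirnov comparison of identification scores between the two groups is the
QC check that the excluded group skews to lower-confidence matches.

Two scoring modes mirror the two phases of the workflow: ``substitute_E``
replaces phospho residues by glutamic acid before scoring (the discovery
step with a phospho-blind predictor — phosphate and glutamate share a
negatively charged side chain), while ``native23`` scores the 23-letter
sequence with a phospho-aware model (the benchmark step).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alphabet import PARENT
from .peptidome_io import ModPeptide, PSMRecord, Proteome, SampleManifest
from .pwm import AlleleModel, CoreAssignment, percent_rank, score_peptide

__all__ = [
    "AssignmentResult",
    "Interaction",
    "AssignmentOutcome",
    "PeptidomeSummary",
    "substitute_phospho_as_glu",
    "assign_peptide",
    "assign_all",
    "qc_score_separation",
    "summarize_peptidome",
    "unique_peptides",
    "random_peptide_control",
]


def substitute_phospho_as_glu(peptide) -> str:
    """Replace every phosphorylated residue by glutamic acid (E).

    Accepts a :class:`ModPeptide` or a mod string; returns a 20-letter
    string of the same length.  Idempotent.
    """
    mod = peptide.mod_sequence if isinstance(peptide, ModPeptide) else str(peptide)
    return "".join("E" if c in PARENT else c for c in mod)


@dataclass
class AssignmentResult:
    """One peptide assigned (or not) to the alleles of one sample."""

    peptide: ModPeptide
    sample_id: str
    assigned_alleles: list[CoreAssignment] = field(default_factory=list)

    @property
    def status(self) -> str:
        return "assigned" if self.assigned_alleles else "unassigned"


@dataclass(frozen=True)
class Interaction:
    """A (peptide, allele) pair passing the %rank cutoff in one sample."""

    sample_id: str
    allele: str
    peptide: ModPeptide
    core_offset: int
    core: str
    raw_score: float
    percent_rank: float


def assign_peptide(
    peptide: ModPeptide,
    sample: SampleManifest,
    models: dict[str, AlleleModel],
    cutoff: float = 10.0,
    mode: str = "substitute_E",
) -> AssignmentResult:
    """Score a peptide against every allele of its sample.

    Alleles with %rank <= ``cutoff`` (inclusive boundary) are kept, sorted
    by %rank ascending, each with its best 9-mer core.  A sample allele
    without a trained model is an error naming the allele.
    """
    assigned: list[CoreAssignment] = []
    for allele in sample.alleles:
        if allele not in models:
            raise KeyError(f"no model for allele {allele!r} of sample {sample.sample_id!r}")
        model = models[allele]
        ca = score_peptide(model, peptide, mode=mode)
        rank = percent_rank(model, ca.raw_score, len(peptide))
        if rank <= cutoff:
            assigned.append(
                CoreAssignment(
                    peptide=ca.peptide,
                    allele=allele,
                    core_offset=ca.core_offset,
                    core=ca.core,
                    raw_score=ca.raw_score,
                    percent_rank=rank,
                )
            )
    assigned.sort(key=lambda c: c.percent_rank)
    return AssignmentResult(peptide=peptide, sample_id=sample.sample_id, assigned_alleles=assigned)


@dataclass
class AssignmentOutcome:
    """Partition of filtered PSMs into assigned and unassigned, with interactions."""

    results: list[AssignmentResult]
    interactions: list[Interaction]
    assigned_psms: list[PSMRecord]
    unassigned_psms: list[PSMRecord]

    @property
    def excluded_fraction(self) -> float:
        total = len(self.assigned_psms) + len(self.unassigned_psms)
        return len(self.unassigned_psms) / total if total else float("nan")


def assign_all(
    psms,
    manifests: dict[str, SampleManifest],
    models: dict[str, AlleleModel],
    cutoff: float = 10.0,
    mode: str = "substitute_E",
    best_only: bool = False,
) -> AssignmentOutcome:
    """Assign every PSM to the alleles of its sample.

    ``best_only`` keeps only the top-ranked passing allele per peptide
    (motif-membership variant); the default keeps all passing alleles,
    matching interaction-level counting.
    """
    results, interactions, assigned, unassigned = [], [], [], []
    for rec in psms:
        sample = manifests[rec.sample_id]
        res = assign_peptide(rec.peptide, sample, models, cutoff=cutoff, mode=mode)
        results.append(res)
        if res.assigned_alleles:
            assigned.append(rec)
            keep = res.assigned_alleles[:1] if best_only else res.assigned_alleles
            for ca in keep:
                interactions.append(
                    Interaction(
                        sample_id=rec.sample_id,
                        allele=ca.allele,
                        peptide=rec.peptide,
                        core_offset=ca.core_offset,
                        core=ca.core,
                        raw_score=ca.raw_score,
                        percent_rank=ca.percent_rank,
                    )
                )
        else:
            unassigned.append(rec)
    return AssignmentOutcome(
        results=results,
        interactions=interactions,
        assigned_psms=assigned,
        unassigned_psms=unassigned,
    )


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float


def qc_score_separation(assigned, unassigned) -> dict[str, KSResult]:
    """Two-sample KS test of assigned vs unassigned PSM score distributions.

    Returns one result per score type (``peptide_score``, ``delta_score``).
    """
    if not assigned or not unassigned:
        raise ValueError("both the assigned and unassigned groups must be non-empty")
    out = {}
    for attr in ("peptide_score", "delta_score"):
        a = [getattr(r, attr) for r in assigned]
        b = [getattr(r, attr) for r in unassigned]
        res = stats.ks_2samp(a, b)
        out[attr] = KSResult(statistic=float(res.statistic), p_value=float(res.pvalue))
    return out


def unique_peptides(interactions) -> list[ModPeptide]:
    """Unique ligands over interactions, keyed by (sequence, phosphosite set)."""
    seen: dict = {}
    for x in interactions:
        pep = x.peptide if isinstance(x, Interaction) else x
        seen.setdefault(pep.key, pep)
    return list(seen.values())


@dataclass
class PeptidomeSummary:
    """Length and phosphosite-multiplicity histograms with headline counts.

    Histograms count unique modified peptides; ``n_interactions`` counts
    (peptide, allele, sample) rows.
    """

    length_hist: Counter
    phospho_count_hist: Counter
    n_unique_peptides: int
    n_interactions: int
    n_alleles: int

    @property
    def phospho_count_fractions(self) -> dict[int, float]:
        total = sum(self.phospho_count_hist.values())
        return {k: v / total for k, v in sorted(self.phospho_count_hist.items())}


def summarize_peptidome(interactions) -> PeptidomeSummary:
    peptides = unique_peptides(interactions)
    return PeptidomeSummary(
        length_hist=Counter(len(p) for p in peptides),
        phospho_count_hist=Counter(p.n_phospho for p in peptides),
        n_unique_peptides=len(peptides),
        n_interactions=len(interactions),
        n_alleles=len({x.allele for x in interactions}),
    )


def random_peptide_control(
    catalogue,
    proteome: Proteome,
    manifests: dict[str, SampleManifest],
    models: dict[str, AlleleModel],
    length_population,
    n: int,
    seed: int = 0,
    cutoff: float = 10.0,
    mode: str = "substitute_E",
) -> AssignmentOutcome:
    """Assignment of random phosphosite-pool peptides (expected mostly excluded).

    Draws ``n`` peptides around catalogue phosphosites with lengths sampled
    with replacement from ``length_population`` (the observed ligand
    lengths), attributes each to a random sample, and runs the same
    assignment as the real data.  The exclusion fraction of this control is
    the baseline against which the observed exclusion rate is judged.
    """
    from .benchmark import sample_negatives

    rng = np.random.default_rng(seed)
    lengths = np.asarray(list(length_population))
    peptides = sample_negatives(
        catalogue,
        proteome,
        n=n,
        seed=int(rng.integers(2**31)),
        length_sampler=lambda r: int(r.choice(lengths)),
    )
    sample_ids = sorted(manifests)
    psms = [
        PSMRecord(
            peptide=pep,
            peptide_score=100.0,
            delta_score=100.0,
            localization_probs=(1.0,) * pep.n_phospho,
            sample_id=sample_ids[int(rng.integers(len(sample_ids)))],
        )
        for pep in peptides
    ]
    return assign_all(psms, manifests, models, cutoff=cutoff, mode=mode)
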