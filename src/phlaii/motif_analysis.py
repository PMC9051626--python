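"""Binding-motif construction and comparison.

Per allele, two display motifs are built from predicted 9-mer binding
cores: one from unmodified ligands and one from phosphorylated ligands,
the latter restricted to peptides whose phosphorylated residue falls
inside the binding core.  Display motifs are pure observed frequencies
(zero pseudocount), unlike the pseudocounted predictor PWMs.

Motif similarity is quantified as the Euclidean distance between
frequency matrices after dropping the phospho rows of the phospho motif
and renormalizing, and the intra-allele vs inter-allele distance
comparison is a one-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alphabet import PARENT
from .pwm import CORE_LENGTH, PWM, count_matrix

__all__ = [
    "MotifPair",
    "DistanceTestResult",
    "build_motif",
    "build_motif_pairs",
    "renormalize_drop_phospho",
    "pwm_distance",
    "intra_vs_inter_distance_test",
]


def build_motif(cores, restrict_phospho_in_core: bool = False) -> PWM | None:
    """Build a display PWM (zero pseudocount) from aligned 9-mer cores.

    With ``restrict_phospho_in_core`` set, cores carrying no phospho
    residue within the 9-mer (peptides phosphorylated only in the flanking
    regions, or not at all) are dropped before counting.  If no core
    survives, the motif is flagged empty and ``None`` is returned.
    """
    cores = list(cores)
    if restrict_phospho_in_core:
        cores = [c for c in cores if any(ch in PARENT for ch in c)]
    if not cores:
        warnings.warn("no cores left after in-core phospho restriction: empty motif", stacklevel=2)
        return None
    counts = count_matrix(cores)
    n = counts[0].sum()
    return PWM(matrix=counts / n, pseudo_weight=0.0, n_training_cores=int(n))


@dataclass
class MotifPair:
    """Unmodified and phospho motifs of one allele with the three core counts."""

    allele: str
    pwm_unmod: PWM | None
    pwm_phos: PWM | None
    n_unmod: int
    n_phos_all: int
    n_phos_core: int


def build_motif_pairs(unmod_interactions, phos_interactions) -> list[MotifPair]:
    """Per-allele motif pairs from unmodified and phosphorylated interactions.

    ``n_phos_all`` counts all phosphopeptide cores of the allele;
    ``n_phos_core`` the subset with the phosphosite inside the core, from
    which alone the phospho motif is built.
    """
    by_allele_unmod: dict[str, list[str]] = {}
    by_allele_phos: dict[str, list[str]] = {}
    for x in unmod_interactions:
        by_allele_unmod.setdefault(x.allele, []).append(x.core)
    for x in phos_interactions:
        by_allele_phos.setdefault(x.allele, []).append(x.core)
    pairs = []
    for allele in sorted(set(by_allele_unmod) | set(by_allele_phos)):
        unmod = by_allele_unmod.get(allele, [])
        phos = by_allele_phos.get(allele, [])
        phos_core = [c for c in phos if any(ch in PARENT for ch in c)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pwm_unmod = build_motif(unmod) if unmod else None
            pwm_phos = build_motif(phos, restrict_phospho_in_core=True) if phos else None
        pairs.append(
            MotifPair(
                allele=allele,
                pwm_unmod=pwm_unmod,
                pwm_phos=pwm_phos,
                n_unmod=len(unmod),
                n_phos_all=len(phos),
                n_phos_core=len(phos_core),
            )
        )
    return pairs


def renormalize_drop_phospho(pwm: PWM) -> PWM:
    """Project a 9 x 23 PWM onto the 20 canonical symbols and renormalize.

    Each position's canonical frequencies are divided by their sum, so the
    result is a proper 9 x 20 frequency matrix.  A position whose entire
    mass sits on phospho symbols is degenerate and raises.
    """
    if pwm.n_symbols == 20:
        return pwm
    canonical = pwm.matrix[:, :20]
    mass = canonical.sum(axis=1)
    if np.any(mass <= 0):
        bad = int(np.argmin(mass))
        raise ValueError(f"position P{bad + 1} has all its mass on phospho symbols")
    return PWM(
        matrix=canonical / mass[:, None],
        pseudo_weight=pwm.pseudo_weight,
        n_training_cores=pwm.n_training_cores,
    )


def pwm_distance(p: PWM, q: PWM) -> float:
    """Euclidean distance between two frequency matrices of equal shape."""
    if p.matrix.shape != q.matrix.shape:
        raise ValueError(f"PWM shapes differ: {p.matrix.shape} vs {q.matrix.shape}")
    return float(np.sqrt(((p.matrix - q.matrix) ** 2).sum()))


@dataclass
class DistanceTestResult:
    """Intra- vs inter-allele phospho/unmodified motif distances."""

    alleles: list[str]
    intra: np.ndarray
    inter: np.ndarray
    p_value: float
    degenerate: bool = False


def intra_vs_inter_distance_test(pairs, min_phos_core: int = 10) -> DistanceTestResult:
    """One-sided rank-sum test that intra-allele motif distances are smaller.

    For each allele the intra distance compares its renormalized phospho
    motif with its own unmodified motif; inter distances compare it with
    every other allele's unmodified motif (n_alleles * (n_alleles - 1)
    values).  Only the phospho side is renormalized: unmodified motifs
    carry no phospho mass by construction.  Alleles with fewer than
    ``min_phos_core`` in-core phosphopeptides are excluded as unstable.
    """
    usable = [
        p
        for p in pairs
        if p.pwm_unmod is not None and p.pwm_phos is not None and p.n_phos_core >= min_phos_core
    ]
    if len(usable) < 2:
        raise ValueError(f"need at least 2 alleles with usable motif pairs, got {len(usable)}")
    phos20 = {p.allele: renormalize_drop_phospho(p.pwm_phos) for p in usable}
    unmod20 = {p.allele: renormalize_drop_phospho(p.pwm_unmod) for p in usable}
    alleles = [p.allele for p in usable]
    intra = np.array([pwm_distance(phos20[a], unmod20[a]) for a in alleles])
    inter = np.array(
        [pwm_distance(phos20[a], unmod20[b]) for a in alleles for b in alleles if a != b]
    )
    if np.ptp(np.concatenate([intra, inter])) == 0:
        return DistanceTestResult(alleles, intra, inter, p_value=float("nan"), degenerate=True)
    p = stats.mannwhitneyu(intra, inter, alternative="less").pvalue
    return DistanceTestResult(alleles, intra, inter, p_value=float(p))
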