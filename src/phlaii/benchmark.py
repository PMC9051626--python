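"""Leave-one-sample-out cross-validation of the phospho-aware predictor.

Each MS sample is held out in turn: per-allele models are retrained on the
remaining interactions with every phosphopeptide of the held-out sample
removed from training, the held-out positives plus a five-fold excess of
phosphosite-pool negatives are scored against the held-out sample's
alleles (per-peptide score = best %rank across those alleles), and
AUC / MCC / F1 are reported per fold and predictor arm.  The native
23-letter arm and the phospho-to-glutamate substitution arm share folds
and negatives, so paired tests across samples are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .assignment import Interaction, substitute_phospho_as_glu
from .peptidome_io import ModPeptide, PhosphositeCatalogue, Proteome, SampleManifest
from .pwm import (
    AlleleModel,
    background_frequencies,
    calibrate,
    percent_rank,
    score_peptide,
    train_allele_model,
)

__all__ = [
    "BenchmarkFold",
    "ArmMetrics",
    "PairedTestResult",
    "sample_negatives",
    "run_loso",
    "compute_auc",
    "compute_mcc_f1",
    "compare_predictor_arms",
]


def sample_negatives(
    catalogue: PhosphositeCatalogue,
    proteome: Proteome,
    n: int,
    seed: int = 0,
    length_range: tuple[int, int] = (12, 25),
    exclude_keys=frozenset(),
    length_sampler=None,
    max_attempts_factor: int = 200,
) -> list[ModPeptide]:
    """Draw random phosphopeptides around known phosphosites.

    Each negative is built by uniformly choosing a catalogue phosphosite, a
    peptide length in ``length_range`` (or from ``length_sampler``) and the
    position of the site within the peptide, then slicing the source
    protein; draws whose slice exceeds the protein bounds are rejected and
    resampled.  Peptides whose (sequence, phosphosite) key is in
    ``exclude_keys`` (the positives) are rejected.  Deterministic per seed.
    """
    if not len(catalogue):
        raise ValueError("phosphosite catalogue is empty")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    out: list[ModPeptide] = []
    attempts = 0
    max_attempts = max(1, n) * max_attempts_factor
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(f"could not draw {n} negatives in {max_attempts} attempts")
        pid, pos, res = catalogue.entries[int(rng.integers(len(catalogue.entries)))]
        length = length_sampler(rng) if length_sampler else int(rng.integers(lo, hi + 1))
        offset = int(rng.integers(0, length))  # position of the site within the peptide
        start = pos - offset
        prot = proteome[pid]
        if start < 0 or start + length > len(prot):
            continue
        seq = prot[start : start + length]
        if any(c not in "ACDEFGHIKLMNPQRSTVWY" for c in seq):
            continue
        pep = ModPeptide(seq, frozenset({offset}), (pid,))
        if pep.key in exclude_keys:
            continue
        out.append(pep)
    return out


def compute_auc(scores_pos, scores_neg, lower_is_better: bool = True) -> float:
    """ROC AUC as the Mann-Whitney probability, ties counted 1/2.

    Equals the fraction of (positive, negative) pairs where the positive is
    better ranked, counting ties as half a win; invariant under strictly
    monotone score transforms.
    """
    pos = np.asarray(list(scores_pos), dtype=float)
    neg = np.asarray(list(scores_neg), dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2  # pairs where pos > neg
    auc_higher = u / (len(pos) * len(neg))
    return float(1.0 - auc_higher) if lower_is_better else float(auc_higher)


@dataclass(frozen=True)
class MccF1:
    mcc: float
    f1: float
    mcc_flagged: bool = False  # a confusion-matrix marginal was zero


def compute_mcc_f1(
    scores_pos, scores_neg, threshold: float = 5.0, lower_is_better: bool = True
) -> MccF1:
    """Matthews correlation and F1 at a fixed %rank binder threshold.

    A peptide is called a binder iff its %rank <= ``threshold``.  When a
    marginal of the confusion matrix is zero the MCC is undefined and
    reported as 0 with a flag.
    """
    pos = np.asarray(list(scores_pos), dtype=float)
    neg = np.asarray(list(scores_neg), dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score lists must be non-empty")
    if lower_is_better:
        tp = int((pos <= threshold).sum())
        fp = int((neg <= threshold).sum())
    else:
        tp = int((pos >= threshold).sum())
        fp = int((neg >= threshold).sum())
    fn = len(pos) - tp
    tn = len(neg) - fp
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc, flagged = 0.0, True
    else:
        mcc, flagged = (tp * tn - fp * fn) / np.sqrt(denom), False
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return MccF1(mcc=float(mcc), f1=float(f1), mcc_flagged=flagged)


@dataclass(frozen=True)
class ArmMetrics:
    auc: float
    mcc: float
    f1: float
    mcc_flagged: bool = False


@dataclass
class BenchmarkFold:
    """One leave-one-sample-out fold with per-arm metrics."""

    held_out_sample: str
    n_train: int
    n_positives: int
    n_negatives: int
    metrics: dict[str, ArmMetrics] = field(default_factory=dict)


def _train_fold_models(
    train_interactions,
    alleles,
    proteome,
    background,
    mode: str,
    pseudo_weight: float,
    calibration_n: int,
    seed: int,
) -> dict[str, AlleleModel]:
    models = {}
    for allele in alleles:
        cores = [x.core for x in train_interactions if x.allele == allele]
        if mode == "substitute_E":
            cores = [substitute_phospho_as_glu(c) for c in cores]
        if not cores:
            raise ValueError(f"no training cores for allele {allele!r}")
        model = train_allele_model(
            cores, background=background, pseudo_weight=pseudo_weight, allele=allele
        )
        calibrate(model, proteome, n_per_length=calibration_n, seed=seed)
        models[allele] = model
    return models


def _best_rank(peptide, alleles, models, mode) -> float:
    ranks = []
    for allele in alleles:
        model = models[allele]
        ca = score_peptide(model, peptide, mode=mode)
        ranks.append(percent_rank(model, ca.raw_score, len(peptide)))
    return min(ranks)


def run_loso(
    manifests: dict[str, SampleManifest],
    interactions: list[Interaction],
    proteome: Proteome,
    catalogue: PhosphositeCatalogue,
    negatives_factor: int = 5,
    seed: int = 0,
    rank_threshold: float = 5.0,
    pseudo_weight: float = 5.0,
    calibration_n: int = 1000,
    arms: tuple[str, ...] = ("native23", "substitute_E"),
) -> list[BenchmarkFold]:
    """Leave-one-sample-out benchmark of the phospho predictor.

    ``interactions`` supplies both the training cores (unmodified and
    phosphorylated) and the per-sample phosphopeptide positives.  In each
    fold, every phosphopeptide found in the held-out sample is removed from
    training in *all* its occurrences (leakage is asserted), negatives are
    drawn once per fold with a fold-derived seed and shared across arms,
    and samples with zero positives are skipped with a warning.
    """
    import warnings

    if len(manifests) < 2:
        raise ValueError("leave-one-sample-out needs at least 2 samples")
    background = background_frequencies(proteome)
    positive_keys_by_sample: dict[str, set] = {}
    for x in interactions:
        if x.peptide.n_phospho > 0:
            positive_keys_by_sample.setdefault(x.sample_id, set()).add(x.peptide.key)
    folds = []
    for fold_index, sample_id in enumerate(sorted(manifests)):
        sample = manifests[sample_id]
        held_keys = positive_keys_by_sample.get(sample_id, set())
        if not held_keys:
            warnings.warn(f"sample {sample_id!r} has no phosphopeptide positives; fold skipped")
            continue
        train = [
            x
            for x in interactions
            if not (x.peptide.n_phospho > 0 and x.peptide.key in held_keys)
        ]
        assert all(
            not (x.peptide.n_phospho > 0 and x.peptide.key in held_keys) for x in train
        ), "LOSO leakage: a held-out phosphopeptide remained in the training set"
        positives = list(
            {
                x.peptide.key: x.peptide
                for x in interactions
                if x.sample_id == sample_id and x.peptide.n_phospho > 0
            }.values()
        )
        negatives = sample_negatives(
            catalogue,
            proteome,
            n=negatives_factor * len(positives),
            seed=seed + fold_index,
            exclude_keys=held_keys,
        )
        fold = BenchmarkFold(
            held_out_sample=sample_id,
            n_train=len(train),
            n_positives=len(positives),
            n_negatives=len(negatives),
        )
        for arm in arms:
            models = _train_fold_models(
                train,
                sample.alleles,
                proteome,
                background,
                mode=arm,
                pseudo_weight=pseudo_weight,
                calibration_n=calibration_n,
                seed=seed + fold_index,
            )
            pos_ranks = [_best_rank(p, sample.alleles, models, arm) for p in positives]
            neg_ranks = [_best_rank(p, sample.alleles, models, arm) for p in negatives]
            auc = compute_auc(pos_ranks, neg_ranks)
            mf = compute_mcc_f1(pos_ranks, neg_ranks, threshold=rank_threshold)
            fold.metrics[arm] = ArmMetrics(
                auc=auc, mcc=mf.mcc, f1=mf.f1, mcc_flagged=mf.mcc_flagged
            )
        folds.append(fold)
    return folds


@dataclass(frozen=True)
class PairedTestResult:
    p_value: float
    n_effective: int  # pairs remaining after dropping zero differences
    flagged: bool = False  # all differences were zero


def compare_predictor_arms(metrics_a, metrics_b) -> PairedTestResult:
    """Paired two-sided Wilcoxon signed-rank test between per-sample metrics.

    Zero differences are dropped; if every pair is tied the test is
    degenerate and p = 1 is returned flagged.
    """
    a = np.asarray(list(metrics_a), dtype=float)
    b = np.asarray(list(metrics_b), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric lists must have equal length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if len(nonzero) == 0:
        return PairedTestResult(p_value=1.0, n_effective=0, flagged=True)
    res = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return PairedTestResult(p_value=float(res.pvalue), n_effective=len(nonzero))
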