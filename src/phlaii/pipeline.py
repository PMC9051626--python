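"""End-to-end convenience wrappers over the pipeline stages.

The discovery workflow mirrors the two-phase design of the analysis: train
per-allele models on unmodified ligands of monoallelic samples, filter the
raw PSM table, assign every filtered phosphopeptide to the alleles of its
sample with the phospho-to-glutamate substitution, then hand the resulting
interactions to the motif, positional and kinase-motif analyses and to the
leave-one-sample-out benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

from .assignment import AssignmentOutcome, assign_all
from .peptidome_io import PSMRecord, Proteome, filter_psms
from .pwm import AlleleModel, background_frequencies, calibrate, train_allele_model
from .synth import SynthWorld

__all__ = [
    "train_models_from_cores",
    "discovery_models_from_world",
    "interactions_from_truth",
    "run_discovery",
]


def interactions_from_truth(world: SynthWorld, kinds=("ligand_phos", "ligand_unmod")):
    """Ground-truth interactions from a world's ledger (no predictor involved).

    Useful to feed downstream analyses or the benchmark with the generating
    truth instead of discovered assignments.
    """
    from .assignment import Interaction
    from .peptidome_io import ModPeptide

    out = []
    for t in world.truth:
        if t.kind not in kinds:
            continue
        pep = ModPeptide.from_mod_string(t.mod_sequence, (t.protein_id,))
        out.append(
            Interaction(
                sample_id=t.sample_id,
                allele=t.allele,
                peptide=pep,
                core_offset=t.core_offset,
                core=t.mod_sequence[t.core_offset : t.core_offset + 9],
                raw_score=0.0,
                percent_rank=0.0,
            )
        )
    return out


def train_models_from_cores(
    cores_by_allele: dict[str, list[str]],
    proteome: Proteome,
    pseudo_weight: float = 5.0,
    calibration_n: int = 10_000,
    seed: int = 0,
    phospho_prior: float = 0.01,
) -> dict[str, AlleleModel]:
    """Train and calibrate one model per allele from aligned 9-mer cores."""
    background = background_frequencies(proteome, phospho_prior=phospho_prior)
    models = {}
    for allele in sorted(cores_by_allele):
        model = train_allele_model(
            cores_by_allele[allele],
            background=background,
            pseudo_weight=pseudo_weight,
            allele=allele,
        )
        calibrate(model, proteome, n_per_length=calibration_n, seed=seed)
        models[allele] = model
    return models


def discovery_models_from_world(
    world: SynthWorld, calibration_n: int = 2000, seed: int = 0, pseudo_weight: float = 5.0
) -> dict:
    """Discovery-phase models: trained on unmodified monoallelic ligand cores.

    Emulates having a pre-existing unmodified-ligand predictor before any
    phosphopeptide is assigned, using the ground-truth cores of the
    monoallelic samples' unmodified ligands.
    """
    mono_samples = {
        sid for sid, m in world.manifests.items() if len(m.alleles) == 1
    }
    cores_by_allele: dict[str, list[str]] = {a: [] for a in world.alleles}
    for t in world.truth:
        if t.kind == "ligand_unmod" and t.sample_id in mono_samples:
            cores_by_allele[t.allele].append(
                t.mod_sequence[t.core_offset : t.core_offset + 9]
            )
    cores_by_allele = {a: c for a, c in cores_by_allele.items() if c}
    return train_models_from_cores(
        cores_by_allele,
        world.proteome,
        pseudo_weight=pseudo_weight,
        calibration_n=calibration_n,
        seed=seed,
    )


@dataclass
class DiscoveryResult:
    filtered: list[PSMRecord]
    outcome: AssignmentOutcome

    @property
    def interactions(self):
        return self.outcome.interactions


def run_discovery(
    psms,
    manifests,
    models,
    cutoff: float = 10.0,
    mode: str = "substitute_E",
    min_score: float = 40.0,
    min_delta: float = 10.0,
    min_locprob: float = 0.75,
    len_range=(12, 25),
) -> DiscoveryResult:
    """Filter a PSM table and assign every surviving peptide to its sample's alleles."""
    filtered = filter_psms(
        psms,
        min_score=min_score,
        min_delta=min_delta,
        min_locprob=min_locprob,
        len_range=len_range,
    )
    outcome = assign_all(filtered, manifests, models, cutoff=cutoff, mode=mode)
    return DiscoveryResult(filtered=filtered, outcome=outcome)
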