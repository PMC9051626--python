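"""Synthetic immunopeptidomics worlds with known ground truth.

Generates every input the pipeline consumes — a proteome, per-sample
identification tables with planted HLA-II ligands and contaminant PSMs, a
sample manifest, and a phosphosite catalogue — from planted per-allele
binding motifs, so that every downstream analysis can be checked against
the generating truth.

The generator's defaults emulate the statistical structure of real HLA-II
phosphopeptidome data: ligand lengths peak at 15-mers within 12-25,
~85/13/1% mono/di/tri-phosphorylation, phosphosites split ~60/40 between
binding core and flanking regions with a mid-core peak and P1 depletion,
terminal flanking phosphosites biased ~63/37 to the C-terminus with the
third N-terminal position favoured, a proline-directed kinase signature
([pS/pT]P) present at ~7.4% among ligand phosphosites versus ~32% in the
phosphoproteome catalogue, and contaminant PSMs drawn from lower
identification-score distributions than true ligands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AA20, INDEX, PHOSPHORYLATABLE, to_mod_string
from .peptidome_io import (
    ModPeptide,
    PhosphositeCatalogue,
    Proteome,
    PSMRecord,
    SampleManifest,
    write_manifest,
    write_psm_table,
)
from .pwm import CORE_LENGTH, HUMAN_AA_FREQUENCIES

__all__ = [
    "SynthConfig",
    "TruthRecord",
    "SynthWorld",
    "ANCHOR_POOL",
    "generate_world",
    "planted_pwm20",
    "planted_pwm23",
    "phospho_anchor_pwm23",
    "sample_cores_from_pwm",
]

#: Anchor preferences (position -> two favoured residues) for up to ten
#: distinct planted alleles, at the canonical anchor positions P1/P4/P6/P9.
ANCHOR_POOL = [
    {0: "YF", 3: "ND", 5: "ST", 8: "LV"},
    {0: "LI", 3: "DE", 5: "KR", 8: "AS"},
    {0: "WF", 3: "QE", 5: "NH", 8: "IV"},
    {0: "VM", 3: "KR", 5: "DE", 8: "YF"},
    {0: "FY", 3: "TS", 5: "RK", 8: "MV"},
    {0: "IL", 3: "GA", 5: "EQ", 8: "FW"},
    {0: "MW", 3: "HN", 5: "AG", 8: "KR"},
    {0: "AV", 3: "RK", 5: "YF", 8: "DE"},
    {0: "KH", 3: "FY", 5: "VL", 8: "NQ"},
    {0: "DE", 3: "LV", 5: "TS", 8: "HW"},
]

_BG20 = np.array([HUMAN_AA_FREQUENCIES[a] for a in AA20])
_BG20 = _BG20 / _BG20.sum()

# 23-letter background for scoring phospho-bearing planted PWMs: phospho
# symbols carry their parent's frequency times a 1% phospho prior.
_BG23 = np.concatenate([_BG20, [_BG20[INDEX["S"]], _BG20[INDEX["T"]], _BG20[INDEX["Y"]]]])
_BG23[20:] *= 0.01
_BG23 = _BG23 / _BG23.sum()


@dataclass
class SynthConfig:
    """Study conditions for a synthetic world."""

    seed: int = 0
    n_alleles: int = 6
    n_polyallelic_samples: int = 4
    alleles_per_poly: int = 3
    n_phospho_per_sample: int = 80
    n_unmod_per_sample: int = 120
    contaminant_fraction: float = 0.48
    #: P(1, 2, 3 phosphosites) per phosphopeptide.
    multiplicity: tuple[float, ...] = (0.854, 0.133, 0.013)
    #: P(a phosphosite falls in the binding core rather than a PFR).
    in_core_prob: float = 0.6
    #: placement over P1..P9 given in-core (depleted at P1, peak at P5).
    core_position_weights: tuple[float, ...] = (
        0.02, 0.09, 0.12, 0.13, 0.20, 0.15, 0.13, 0.10, 0.06,
    )
    #: P(a PFR phosphosite sits in the C-terminal rather than N-terminal region).
    cterm_prob: float = 0.63
    #: placement over the first three peptide positions given N-terminal.
    nterm_position_weights: tuple[float, ...] = (0.24, 0.305, 0.455)
    #: S/T/Y mixture of phosphorylated residues.
    phospho_residue_mixture: tuple[float, ...] = (0.80, 0.15, 0.05)
    #: P(residue after a ligand phosphosite is proline) — the [pS/pT]P signal.
    p_next_proline_phospho: float = 0.0744
    #: fraction of catalogue phosphosites followed by proline (phosphoproteome).
    catalogue_next_proline_rate: float = 0.3202
    n_catalogue_extra: int = 3000
    n_proteins: int = 500
    mean_protein_length: int = 450
    #: peptide length = 12 + Binomial(13, length_p): peak at 15 within 12-25.
    length_p: float = 3 / 13
    #: fraction of contaminant PSMs emitted as 8-11-mers (length-filter fodder).
    short_fraction: float = 0.04
    #: fraction of phosphosites given a localization probability below 0.75.
    locprob_low_fraction: float = 0.08
    #: Beta parameters of well-localized site probabilities.
    locprob_beta: tuple[float, float] = (12.0, 1.0)
    true_score: tuple[float, float] = (120.0, 20.0)
    true_delta: tuple[float, float] = (45.0, 15.0)
    contaminant_score: tuple[float, float] = (85.0, 25.0)
    contaminant_delta: tuple[float, float] = (18.0, 10.0)
    anchor_strength: float = 0.425  # per favoured residue at anchor positions
    #: presentation selection: an emitted ligand's core must score above
    #: this percentile of random background cores under its planted PWM.
    #: MS observes presented peptides only, and presented ligands are
    #: top-percentile binders (the conventional %rank < 1 notion).
    presentation_percentile: float = 99.0
    #: when set, this core position's pocket prefers the phosphate itself:
    #: every allele's PWM puts ``phospho_anchor_mass`` on pS/pT there, and
    #: presentation selection acts on the native phosphorylated core.  Off
    #: by default (phosphosites are then glutamate-like passengers).
    phospho_anchor_position: int | None = None
    phospho_anchor_mass: float = 0.6

    @classmethod
    def noiseless(cls, **overrides) -> "SynthConfig":
        """Conditions under which every emitted PSM is a confidently
        identified, well-localized planted ligand: no contaminants, no
        sub-threshold localization noise, and identification-score
        distributions clear of the filter thresholds."""
        defaults = dict(
            contaminant_fraction=0.0,
            locprob_low_fraction=0.0,
            locprob_beta=(300.0, 1.0),
            true_delta=(60.0, 12.0),
        )
        defaults.update(overrides)
        return cls(**defaults)

    def __post_init__(self):
        if abs(sum(self.multiplicity) - 1) > 1e-9:
            raise ValueError("multiplicity mixture must sum to 1")
        if abs(sum(self.core_position_weights) - 1) > 1e-9:
            raise ValueError("core position weights must sum to 1")
        if self.n_alleles > len(ANCHOR_POOL):
            raise ValueError(f"at most {len(ANCHOR_POOL)} planted alleles are available")
        if 12 + 13 > self.mean_protein_length:
            raise ValueError("proteins too short for ligand embedding")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one emitted PSM."""

    sample_id: str
    kind: str  # ligand_phos | ligand_unmod | contaminant
    allele: str  # "" for contaminants
    mod_sequence: str
    core_offset: int  # -1 for contaminants
    protein_id: str
    start: int

    @property
    def key(self):
        pep = ModPeptide.from_mod_string(self.mod_sequence)
        return pep.key


@dataclass
class SynthWorld:
    """A generated world: inputs plus the ground-truth ledger."""

    config: SynthConfig
    alleles: list[str]
    planted_pwms: dict[str, np.ndarray]  # allele -> 9 x 20 core PWM
    proteome: Proteome
    catalogue: PhosphositeCatalogue
    manifests: dict[str, SampleManifest]
    psms: list[PSMRecord]
    truth: list[TruthRecord] = field(default_factory=list)

    def truth_by_key(self) -> dict:
        out: dict = {}
        for t in self.truth:
            out.setdefault(t.key, t)
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.proteome.to_fasta(outdir / "proteome.fasta")
        write_manifest(self.manifests, outdir / "manifest.tsv")
        write_psm_table(self.psms, outdir / "msms.tsv")
        self.catalogue.to_tsv(outdir / "phosphosites.tsv")
        rows = [
            {
                "sample_id": t.sample_id,
                "kind": t.kind,
                "allele": t.allele,
                "mod_sequence": t.mod_sequence,
                "core_offset": t.core_offset,
                "protein_id": t.protein_id,
                "start": t.start,
            }
            for t in self.truth
        ]
        pd.DataFrame(
            rows,
            columns=[
                "sample_id", "kind", "allele", "mod_sequence",
                "core_offset", "protein_id", "start",
            ],
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)


def planted_pwm20(allele_index: int, anchor_strength: float = 0.425) -> np.ndarray:
    """9 x 20 core PWM of a planted allele: anchored at P1/P4/P6/P9."""
    anchors = ANCHOR_POOL[allele_index]
    pwm = np.tile(_BG20, (CORE_LENGTH, 1))
    for pos, residues in anchors.items():
        col = _BG20 * (1 - 2 * anchor_strength)
        for r in residues:
            col[INDEX[r]] += anchor_strength
        pwm[pos] = col
    return pwm / pwm.sum(axis=1, keepdims=True)


def planted_pwm23(
    allele_index: int,
    core_phospho_sites: float = 0.6,
    core_position_weights=SynthConfig.core_position_weights,
    phospho_residue_mixture=(0.80, 0.15, 0.05),
    anchor_strength: float = 0.425,
) -> np.ndarray:
    """Explicit 9 x 23 PWM: the 20-letter core PWM with phospho columns mixed in.

    Position p is phosphorylated with probability
    ``core_phospho_sites * core_position_weights[p]`` (so the expected
    number of in-core phosphosites is ``core_phospho_sites``), the residue
    then drawn from the S/T/Y mixture.
    """
    base = planted_pwm20(allele_index, anchor_strength)
    weights = np.asarray(core_position_weights)
    mixture = np.asarray(phospho_residue_mixture)
    pwm = np.zeros((CORE_LENGTH, 23))
    for p in range(CORE_LENGTH):
        phi = core_phospho_sites * weights[p]
        pwm[p, :20] = (1 - phi) * base[p]
        pwm[p, 20:] = phi * mixture
    return pwm / pwm.sum(axis=1, keepdims=True)


def sample_cores_from_pwm(pwm: np.ndarray, n: int, rng) -> list[str]:
    """Draw ``n`` 9-mer cores columnwise-independently from a PWM.

    The PWM may be 9 x 20 (unmodified cores) or 9 x 23 (cores that can
    carry phospho symbols).
    """
    from .alphabet import ALPHABET23

    symbols = ALPHABET23[: pwm.shape[1]]
    cols = [rng.choice(len(symbols), size=n, p=pwm[p] / pwm[p].sum()) for p in range(CORE_LENGTH)]
    return ["".join(symbols[cols[p][i]] for p in range(CORE_LENGTH)) for i in range(n)]


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------


def _draw_length(cfg: SynthConfig, rng) -> int:
    return 12 + int(rng.binomial(13, cfg.length_p))


def _draw_bg(rng, exclude: str = "") -> str:
    if exclude:
        probs = _BG20.copy()
        for c in exclude:
            probs[INDEX[c]] = 0.0
        probs /= probs.sum()
    else:
        probs = _BG20
    return AA20[int(rng.choice(20, p=probs))]


def _core_placement_weights(cfg: SynthConfig, anchors: dict | None) -> np.ndarray:
    """In-core placement weights with binding selection applied.

    A presented ligand must still bind with its phosphate in place, so
    anchor positions whose favoured residues do not include S/T/Y cannot
    host a phosphosite; their weight is redistributed.
    """
    weights = np.asarray(cfg.core_position_weights, dtype=float).copy()
    if anchors:
        for pos, residues in anchors.items():
            if not set(residues) & set(PHOSPHORYLATABLE):
                weights[pos] = 0.0
    return weights / weights.sum()


def _place_phosphosites(
    cfg: SynthConfig, rng, length: int, offset: int, anchors: dict | None = None
) -> list[int]:
    """Choose distinct phosphosite positions per the placement distribution."""
    k = 1 + int(rng.choice(len(cfg.multiplicity), p=np.asarray(cfg.multiplicity)))
    core_weights = _core_placement_weights(cfg, anchors)
    in_core = lambda i: offset <= i < offset + CORE_LENGTH
    n_side = [i for i in (0, 1, 2) if not in_core(i)]
    c_side = [i for i in (length - 3, length - 2, length - 1) if not in_core(i)]
    chosen: set[int] = set()
    attempts = 0
    while len(chosen) < k and attempts < 100:
        attempts += 1
        if rng.random() < cfg.in_core_prob or not (n_side or c_side):
            pos = offset + int(rng.choice(CORE_LENGTH, p=core_weights))
        else:
            use_c = rng.random() < cfg.cterm_prob
            side = (c_side if use_c else n_side) or (n_side if use_c else c_side)
            if side is c_side:
                pos = side[int(rng.integers(len(side)))]
            else:
                w = np.asarray(cfg.nterm_position_weights)[side]
                pos = side[int(rng.choice(len(side), p=w / w.sum()))]
        chosen.add(pos)
    return sorted(chosen)


def _core_log_odds(pwm: np.ndarray, core: str) -> float:
    bg = _BG23 if pwm.shape[1] == 23 else _BG20
    idx = [INDEX[c] for c in core]
    return float(np.sum(np.log2(np.maximum(pwm[np.arange(CORE_LENGTH), idx], 1e-12) / bg[idx])))


def _presentation_threshold(pwm: np.ndarray, rng, percentile: float, n: int = 500) -> float:
    """Score a planted-PWM core must beat to count as presented.

    The threshold is the given percentile of planted-PWM scores of random
    background 9-mers, so only genuine binders enter the emitted repertoire.
    """
    width = pwm.shape[1]
    bg = _BG23 if width == 23 else _BG20
    from .alphabet import ALPHABET23

    symbols = ALPHABET23[:width]
    bg_cores = [
        "".join(symbols[k] for k in rng.choice(width, size=CORE_LENGTH, p=bg))
        for _ in range(n)
    ]
    scores = [_core_log_odds(pwm, c) for c in bg_cores]
    return float(np.percentile(scores, percentile))


def _draw_presented_core(pwm: np.ndarray, rng, threshold: float) -> str:
    for _ in range(1000):
        core = sample_cores_from_pwm(pwm, 1, rng)[0]
        if _core_log_odds(pwm, core) >= threshold:
            return core
    raise RuntimeError("presentation selection rejected 1000 consecutive cores")


def phospho_anchor_pwm23(
    pwm20: np.ndarray, position: int, mass: float = 0.6, st_split: float = 0.75
) -> np.ndarray:
    """A 9 x 23 PWM whose pocket at ``position`` prefers the phosphate.

    ``mass`` is moved onto pS/pT at that position (split ``st_split`` to
    pS); all other positions keep their canonical columns.
    """
    pwm = np.zeros((CORE_LENGTH, 23))
    pwm[:, :20] = pwm20
    pwm[position, :20] = pwm20[position] * (1 - mass)
    pwm[position, INDEX["s"]] = mass * st_split
    pwm[position, INDEX["t"]] = mass * (1 - st_split)
    return pwm / pwm.sum(axis=1, keepdims=True)


def _make_phospho_ligand(
    cfg: SynthConfig,
    rng,
    pwm20: np.ndarray,
    anchors: dict | None = None,
    threshold: float = -np.inf,
):
    """One phosphorylated ligand: (parent sequence, phospho positions, core offset).

    Presentation selection acts on the peptide as presented: the
    phosphorylated side chain behaves like glutamate in the binding groove,
    so the core is required to beat the presentation threshold with E at
    its phosphosites.  Placements whose phosphate would abolish binding are
    therefore resampled — the mechanism behind the positional specificity
    of phosphosites in presented ligands.
    """
    length = _draw_length(cfg, rng)
    offset = int(rng.integers(0, length - CORE_LENGTH + 1))
    core = _draw_presented_core(pwm20, rng, threshold)
    mixture = np.asarray(cfg.phospho_residue_mixture)
    if pwm20.shape[1] == 23:
        # phospho-anchor mode: the core may already carry its phosphosites
        # and presentation selection has acted on the native core
        seq = [
            _draw_bg(rng) if not (offset <= i < offset + CORE_LENGTH) else core[i - offset]
            for i in range(length)
        ]
        sites = {i for i in range(length) if seq[i].islower()}
        seq = [c.upper() for c in seq]
        if not sites:  # guarantee at least one phosphosite per phosphopeptide
            pfr = [i for i in range(length) if not (offset <= i < offset + CORE_LENGTH)]
            i = pfr[int(rng.integers(len(pfr)))]
            seq[i] = PHOSPHORYLATABLE[int(rng.choice(3, p=mixture))]
            sites = {i}
        for i in sorted(sites):
            if i + 1 < length and (i + 1) not in sites:
                if rng.random() < cfg.p_next_proline_phospho:
                    seq[i + 1] = "P"
                elif seq[i + 1] == "P":
                    seq[i + 1] = _draw_bg(rng, exclude="P")
        return "".join(seq), frozenset(sites), offset
    base = [
        _draw_bg(rng) if not (offset <= i < offset + CORE_LENGTH) else core[i - offset]
        for i in range(length)
    ]
    for _ in range(200):
        seq = list(base)
        sites = _place_phosphosites(cfg, rng, length, offset, anchors)
        for i in sites:
            seq[i] = PHOSPHORYLATABLE[int(rng.choice(3, p=mixture))]
            if i + 1 < length and (i + 1) not in sites:
                if rng.random() < cfg.p_next_proline_phospho:
                    seq[i + 1] = "P"
                elif seq[i + 1] == "P":
                    seq[i + 1] = _draw_bg(rng, exclude="P")
        presented_core = "".join(
            "E" if (i in sites) else seq[i] for i in range(offset, offset + CORE_LENGTH)
        )
        if _core_log_odds(pwm20, presented_core) >= threshold:
            return "".join(seq), frozenset(sites), offset
    raise RuntimeError("no phosphosite placement compatible with presentation found")


def _make_unmod_ligand(cfg: SynthConfig, rng, pwm20: np.ndarray, threshold: float = -np.inf):
    length = _draw_length(cfg, rng)
    offset = int(rng.integers(0, length - CORE_LENGTH + 1))
    core = _draw_presented_core(pwm20, rng, threshold)
    seq = "".join(
        _draw_bg(rng) if not (offset <= i < offset + CORE_LENGTH) else core[i - offset]
        for i in range(length)
    )
    return seq, offset


def _truncnorm(rng, mu, sigma, lo=0.0) -> float:
    x = rng.normal(mu, sigma)
    while x < lo:
        x = rng.normal(mu, sigma)
    return float(x)


def _locprob(cfg: SynthConfig, rng) -> float:
    if cfg.locprob_low_fraction and rng.random() < cfg.locprob_low_fraction:
        return float(rng.uniform(0.3, 0.75))
    return float(min(1.0, rng.beta(*cfg.locprob_beta)))


def generate_world(config: SynthConfig | None = None) -> SynthWorld:
    """Generate a complete synthetic world; byte-reproducible per seed."""
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    alleles = [f"DRB1_SYN_{i + 1:02d}" for i in range(cfg.n_alleles)]
    pwms = {a: planted_pwm20(i, cfg.anchor_strength) for i, a in enumerate(alleles)}
    anchors_by_allele = {a: ANCHOR_POOL[i] for i, a in enumerate(alleles)}
    if cfg.phospho_anchor_position is not None:
        core_pwms = {
            a: phospho_anchor_pwm23(
                pwms[a], cfg.phospho_anchor_position, cfg.phospho_anchor_mass
            )
            for a in alleles
        }
    else:
        core_pwms = pwms
    thresholds = {
        a: _presentation_threshold(core_pwms[a], rng, cfg.presentation_percentile)
        for a in alleles
    }
    thresholds_unmod = {
        a: _presentation_threshold(pwms[a], rng, cfg.presentation_percentile)
        for a in alleles
    }

    # samples: one monoallelic sample per allele plus polyallelic samples
    manifests: dict[str, SampleManifest] = {}
    for i, a in enumerate(alleles):
        sid = f"mono_{i + 1:02d}"
        manifests[sid] = SampleManifest(sid, (a,), capture="DR-only")
    for j in range(cfg.n_polyallelic_samples):
        sid = f"poly_{j + 1:02d}"
        chosen = rng.choice(cfg.n_alleles, size=cfg.alleles_per_poly, replace=False)
        manifests[sid] = SampleManifest(
            sid, tuple(alleles[k] for k in sorted(chosen)), capture="pan-II-only"
        )

    # ligands first, so they can be embedded while the proteome is assembled
    n_cont = int(round(cfg.n_phospho_per_sample * cfg.contaminant_fraction))
    n_true_phos = cfg.n_phospho_per_sample - n_cont
    ligands = []  # (sample_id, kind, allele, seq, phospho, offset)
    for sid in sorted(manifests):
        sample = manifests[sid]
        for _ in range(n_true_phos):
            allele = sample.alleles[int(rng.integers(len(sample.alleles)))]
            seq, sites, offset = _make_phospho_ligand(
                cfg, rng, core_pwms[allele], anchors_by_allele[allele], thresholds[allele]
            )
            ligands.append((sid, "ligand_phos", allele, seq, sites, offset))
        for _ in range(cfg.n_unmod_per_sample):
            allele = sample.alleles[int(rng.integers(len(sample.alleles)))]
            seq, offset = _make_unmod_ligand(
                cfg, rng, pwms[allele], thresholds_unmod[allele]
            )
            ligands.append((sid, "ligand_unmod", allele, seq, frozenset(), offset))

    # proteome: random background proteins with ligands embedded left to right
    lengths = np.minimum(
        rng.geometric(1.0 / cfg.mean_protein_length, size=cfg.n_proteins) + 60, 3000
    )
    proteins = [
        list(AA20[k] for k in rng.choice(20, size=int(L), p=_BG20)) for L in lengths
    ]
    pids = [f"SYNP{i + 1:05d}" for i in range(cfg.n_proteins)]
    cursor = [0] * cfg.n_proteins
    placements = []  # (protein index, start) per ligand
    pi = 0
    for _, _, _, seq, _, _ in ligands:
        tries = 0
        while cursor[pi] + len(seq) + 1 > len(proteins[pi]):
            pi = (pi + 1) % cfg.n_proteins
            tries += 1
            if tries > cfg.n_proteins:
                raise ValueError("proteome too small to embed all ligands")
        start = cursor[pi]
        proteins[pi][start : start + len(seq)] = list(seq)
        cursor[pi] = start + len(seq) + 1
        placements.append((pi, start))
        pi = (pi + 1) % cfg.n_proteins
    proteome = Proteome({pid: "".join(p) for pid, p in zip(pids, proteins)})

    # contaminants: random proteome slices carrying one phosphosite
    contaminants = []  # (sample_id, seq, site, protein index, start)
    for sid in sorted(manifests):
        for _ in range(n_cont):
            while True:
                k = int(rng.integers(cfg.n_proteins))
                prot = proteome[pids[k]]
                length = (
                    int(rng.integers(8, 12))
                    if rng.random() < cfg.short_fraction
                    else _draw_length(cfg, rng)
                )
                lo = cursor[k]  # stay clear of embedded ligand regions
                if len(prot) - length < lo:
                    continue
                start = int(rng.integers(lo, len(prot) - length + 1))
                seq = prot[start : start + length]
                sty = [i for i, c in enumerate(seq) if c in PHOSPHORYLATABLE]
                if sty:
                    site = sty[int(rng.integers(len(sty)))]
                    contaminants.append((sid, seq, site, k, start))
                    break

    # phosphosite catalogue: planted ligand sites plus extra proteome sites,
    # the extras stratified on next-residue proline to emulate the
    # phosphoproteome's proline-directed signature
    entries: list[tuple[str, int, str]] = []
    for (sid, kind, allele, seq, sites, offset), (k, start) in zip(ligands, placements):
        for i in sorted(sites):
            entries.append((pids[k], start + i, seq[i]))
    with_p, without_p = [], []
    for k, pid in enumerate(pids):
        prot = proteome[pid]
        for i, c in enumerate(prot[:-1]):
            if c in PHOSPHORYLATABLE:
                (with_p if prot[i + 1] == "P" else without_p).append((pid, i, c))
    n_with = int(round(cfg.n_catalogue_extra * cfg.catalogue_next_proline_rate))
    n_without = cfg.n_catalogue_extra - n_with
    n_with = min(n_with, len(with_p))
    n_without = min(n_without, len(without_p))
    for pool, n_take in ((with_p, n_with), (without_p, n_without)):
        chosen = rng.choice(len(pool), size=n_take, replace=False)
        entries.extend(pool[i] for i in sorted(chosen))
    catalogue = PhosphositeCatalogue(tuple(dict.fromkeys(entries)))

    # PSM table and truth ledger
    psms: list[PSMRecord] = []
    truth: list[TruthRecord] = []
    for (sid, kind, allele, seq, sites, offset), (k, start) in zip(ligands, placements):
        pep = ModPeptide(seq, sites, (pids[k],))
        psms.append(
            PSMRecord(
                peptide=pep,
                peptide_score=_truncnorm(rng, *cfg.true_score),
                delta_score=_truncnorm(rng, *cfg.true_delta),
                localization_probs=tuple(_locprob(cfg, rng) for _ in sorted(sites)),
                sample_id=sid,
            )
        )
        truth.append(
            TruthRecord(
                sample_id=sid,
                kind=kind,
                allele=allele,
                mod_sequence=to_mod_string(seq, sites),
                core_offset=offset,
                protein_id=pids[k],
                start=start,
            )
        )
    for sid, seq, site, k, start in contaminants:
        pep = ModPeptide(seq, frozenset({site}), (pids[k],))
        psms.append(
            PSMRecord(
                peptide=pep,
                peptide_score=_truncnorm(rng, *cfg.contaminant_score),
                delta_score=_truncnorm(rng, *cfg.contaminant_delta),
                localization_probs=(_locprob(cfg, rng),),
                sample_id=sid,
            )
        )
        truth.append(
            TruthRecord(
                sample_id=sid,
                kind="contaminant",
                allele="",
                mod_sequence=to_mod_string(seq, {site}),
                core_offset=-1,
                protein_id=pids[k],
                start=start,
            )
        )

    return SynthWorld(
        config=cfg,
        alleles=alleles,
        planted_pwms=pwms,
        proteome=proteome,
        catalogue=catalogue,
        manifests=manifests,
        psms=psms,
        truth=truth,
    )
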