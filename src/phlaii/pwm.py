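"""Per-allele position weight matrices over the 23-letter alphabet.

An :class:`AlleleModel` is a 9-position PWM (20 amino acids + pS/pT/pY),
trained from binding cores with background-proportional pseudocounts, that
scores a peptide by the maximum log2 odds over all 9-mer core offsets and
converts raw scores to percentile ranks (%rank, lower = better) against
random proteome peptides of the same length.

This is a single-PWM max-over-offsets scorer: the minimal model consistent
with core prediction, motif construction and %rank thresholding.  Offset
priors and flanking-region terms are deliberate extension points, not
implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AA20, ALPHABET23, INDEX, PARENT, encode
from .peptidome_io import ModPeptide, Proteome

__all__ = [
    "PWM",
    "AlleleModel",
    "CoreAssignment",
    "CORE_LENGTH",
    "count_matrix",
    "background_frequencies",
    "train_allele_model",
    "score_peptide",
    "calibrate",
    "percent_rank",
    "save_model",
    "load_model",
    "save_models",
    "load_models",
]

CORE_LENGTH = 9

#: Calibration lengths: the HLA-II ligand length range after filtering.
CALIBRATION_LENGTHS = tuple(range(12, 26))

#: Amino-acid frequencies of the reviewed human proteome (UniProt), used as
#: the default 20-letter background when no proteome is supplied.
HUMAN_AA_FREQUENCIES = {
    "A": 0.0702, "C": 0.0230, "D": 0.0474, "E": 0.0710, "F": 0.0365,
    "G": 0.0657, "H": 0.0263, "I": 0.0433, "K": 0.0573, "L": 0.0996,
    "M": 0.0213, "N": 0.0359, "P": 0.0631, "Q": 0.0477, "R": 0.0564,
    "S": 0.0833, "T": 0.0536, "V": 0.0597, "W": 0.0122, "Y": 0.0266,
}


@dataclass
class PWM:
    """A 9 x 23 matrix of per-position symbol frequencies.

    ``matrix[p, a]`` is the frequency of alphabet symbol ``a`` at core
    position ``p`` (0-based; user-facing output labels them P1..P9).
    """

    matrix: np.ndarray
    pseudo_weight: float = 0.0
    n_training_cores: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != CORE_LENGTH:
            raise ValueError(f"PWM matrix must be {CORE_LENGTH} x n_symbols, got {self.matrix.shape}")
        if (self.matrix < 0).any():
            raise ValueError("PWM frequencies must be nonnegative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError(f"PWM positions must each sum to 1, got sums {sums}")

    @property
    def n_symbols(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class CoreAssignment:
    """A peptide scored against one allele: best 9-mer core and its score."""

    peptide: ModPeptide
    allele: str
    core_offset: int
    core: str
    raw_score: float
    percent_rank: float | None = None


@dataclass
class AlleleModel:
    """PWM, background and %rank calibration for one HLA-II allele."""

    allele: str
    pwm: PWM
    background: np.ndarray
    calibration: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (len(ALPHABET23),):
            raise ValueError("background must be a 23-vector")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        self._log_odds = None

    @property
    def log_odds(self) -> np.ndarray:
        """9 x 23 matrix of log2(PWM / background), cached."""
        if self._log_odds is None:
            with np.errstate(divide="ignore"):
                self._log_odds = np.log2(self.pwm.matrix / self.background[None, :])
        return self._log_odds

    # thin OO wrappers over the module-level operations
    def score(self, peptide, mode: str = "native23") -> CoreAssignment:
        return score_peptide(self, peptide, mode=mode)

    def percent_rank(self, raw_score: float, length: int) -> float:
        return percent_rank(self, raw_score, length)


def count_matrix(cores) -> np.ndarray:
    """9 x 23 symbol counts over aligned 9-mer cores (mod strings)."""
    cores = list(cores)
    if not cores:
        raise ValueError("need at least one core")
    counts = np.zeros((CORE_LENGTH, len(ALPHABET23)))
    for core in cores:
        if len(core) != CORE_LENGTH:
            raise ValueError(f"core {core!r} is not {CORE_LENGTH} residues long")
        idx = encode(core)
        counts[np.arange(CORE_LENGTH), idx] += 1
    return counts


def background_frequencies(
    proteome: Proteome | None = None, phospho_prior: float = 0.01
) -> np.ndarray:
    """23-letter background frequencies.

    The 20 canonical frequencies come from the supplied proteome (or a fixed
    human-proteome table).  Each phospho symbol receives the frequency of
    its parent residue times ``phospho_prior`` — phospho background
    frequencies cannot be measured from an unmodified proteome, so the prior
    is an explicit, configurable choice — and the 23-vector is renormalized.
    """
    freq20 = np.zeros(20)
    if proteome is None:
        for a, f in HUMAN_AA_FREQUENCIES.items():
            freq20[INDEX[a]] = f
    else:
        for seq in proteome.sequences.values():
            for c in seq:
                if c in INDEX and INDEX[c] < 20:
                    freq20[INDEX[c]] += 1
    freq20 = freq20 / freq20.sum()
    bg = np.zeros(len(ALPHABET23))
    bg[:20] = freq20
    for phos, parent in PARENT.items():
        bg[INDEX[phos]] = freq20[INDEX[parent]] * phospho_prior
    return bg / bg.sum()


def train_allele_model(
    cores,
    background: np.ndarray | None = None,
    pseudo_weight: float = 5.0,
    allele: str = "",
) -> AlleleModel:
    """Train a 9-position PWM from aligned binding cores.

    Frequency of symbol ``a`` at position ``p`` is
    ``(count(a, p) + pseudo_weight * background[a]) / (n + pseudo_weight)``:
    background-proportional pseudocounts keep the rare phospho symbols
    strictly positive.
    """
    if background is None:
        background = background_frequencies()
    background = np.asarray(background, dtype=float)
    counts = count_matrix(cores)
    n = counts[0].sum()
    matrix = (counts + pseudo_weight * background[None, :]) / (n + pseudo_weight)
    pwm = PWM(matrix=matrix, pseudo_weight=pseudo_weight, n_training_cores=int(n))
    return AlleleModel(allele=allele, pwm=pwm, background=background)


def _as_mod_string(peptide) -> str:
    return peptide.mod_sequence if isinstance(peptide, ModPeptide) else str(peptide)


def score_peptide(model: AlleleModel, peptide, mode: str = "native23") -> CoreAssignment:
    """Score a peptide: max log2-odds over all 9-mer core offsets.

    ``mode='native23'`` scores the 23-letter mod string directly;
    ``mode='substitute_E'`` scores with phospho residues replaced by
    glutamic acid (the phospho-blind discovery mode).  The reported core is
    always the native mod-string slice at the best offset; ties break to
    the smallest offset.
    """
    native = _as_mod_string(peptide)
    if len(native) < CORE_LENGTH:
        raise ValueError(f"peptide of length {len(native)} is shorter than the {CORE_LENGTH}-mer core")
    if mode == "substitute_E":
        from .assignment import substitute_phospho_as_glu

        scored = substitute_phospho_as_glu(native)
    elif mode == "native23":
        scored = native
    else:
        raise ValueError(f"unknown scoring mode {mode!r}")
    idx = encode(scored)
    windows = np.lib.stride_tricks.sliding_window_view(idx, CORE_LENGTH)
    scores = model.log_odds[np.arange(CORE_LENGTH)[None, :], windows].sum(axis=1)
    offset = int(np.argmax(scores))  # argmax returns the first max: smallest offset
    pep = peptide if isinstance(peptide, ModPeptide) else ModPeptide.from_mod_string(native)
    return CoreAssignment(
        peptide=pep,
        allele=model.allele,
        core_offset=offset,
        core=native[offset : offset + CORE_LENGTH],
        raw_score=float(scores[offset]),
    )


def _batch_max_scores(model: AlleleModel, idx_rows: np.ndarray) -> np.ndarray:
    """Max-over-offsets scores for a batch of equal-length encoded peptides."""
    windows = np.lib.stride_tricks.sliding_window_view(idx_rows, CORE_LENGTH, axis=1)
    per_offset = model.log_odds[np.arange(CORE_LENGTH)[None, None, :], windows].sum(axis=2)
    return per_offset.max(axis=1)


def calibrate(
    model: AlleleModel,
    proteome: Proteome,
    n_per_length: int = 10_000,
    seed: int = 0,
    lengths=CALIBRATION_LENGTHS,
) -> dict[int, np.ndarray]:
    """Build the %rank calibration table from random proteome peptides.

    For each peptide length, ``n_per_length`` subsequences are drawn
    uniformly over all windows of that length in the proteome, scored, and
    stored sorted ascending.  Deterministic given ``seed``.  The table is
    stored on the model and returned.
    """
    rng = np.random.default_rng(seed)
    prots = [s for _, s in sorted(proteome.items())]
    calibration: dict[int, np.ndarray] = {}
    for length in lengths:
        weights = np.array([max(0, len(p) - length + 1) for p in prots], dtype=float)
        if weights.sum() == 0:
            raise ValueError(f"no protein long enough for calibration length {length}")
        probs = weights / weights.sum()
        choice = rng.choice(len(prots), size=n_per_length, p=probs)
        rows = np.empty((n_per_length, length), dtype=np.intp)
        for i, k in enumerate(choice):
            start = rng.integers(0, len(prots[k]) - length + 1)
            rows[i] = encode(prots[k][start : start + length])
        scores = _batch_max_scores(model, rows)
        calibration[length] = np.sort(scores)
    model.calibration = calibration
    return calibration


def percent_rank(model: AlleleModel, raw_score: float, length: int) -> float:
    """Percentile rank of a raw score among calibration scores of that length.

    ``100 * (1 + #{calibration >= score}) / (N + 1)``; lower is better, and
    the best achievable rank is ``100 / (N + 1)``.
    """
    if length not in model.calibration:
        raise ValueError(f"no calibration for peptide length {length} (allele {model.allele})")
    cal = model.calibration[length]
    n_ge = len(cal) - int(np.searchsorted(cal, raw_score, side="left"))
    return 100.0 * (1 + n_ge) / (len(cal) + 1)


# ---------------------------------------------------------------------------
# Plain-text model serialization (format "phlaii-model 1")
# ---------------------------------------------------------------------------


def save_model(model: AlleleModel, path) -> None:
    lines = [
        "# phlaii-model 1",
        f"allele\t{model.allele}",
        f"pseudo_weight\t{model.pwm.pseudo_weight:g}",
        f"n_training_cores\t{model.pwm.n_training_cores}",
        "alphabet\t" + "".join(ALPHABET23),
        "background\t" + "\t".join(f"{x:.10g}" for x in model.background),
        "pwm",
    ]
    for p in range(CORE_LENGTH):
        lines.append("\t".join(f"{x:.10g}" for x in model.pwm.matrix[p]))
    for length in sorted(model.calibration):
        lines.append(
            f"calibration\t{length}\t"
            + "\t".join(f"{x:.8g}" for x in model.calibration[length])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path) -> AlleleModel:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# phlaii-model 1"):
        raise ValueError(f"{path}: not a phlaii model file")
    header: dict[str, str] = {}
    matrix_rows: list[list[float]] = []
    calibration: dict[int, np.ndarray] = {}
    it = iter(lines[1:])
    for line in it:
        if line == "pwm":
            for _ in range(CORE_LENGTH):
                matrix_rows.append([float(x) for x in next(it).split("\t")])
        elif line.startswith("calibration\t"):
            _, length, *scores = line.split("\t")
            calibration[int(length)] = np.array([float(x) for x in scores])
        elif line.strip():
            key, _, value = line.partition("\t")
            header[key] = value
    pwm = PWM(
        matrix=np.array(matrix_rows),
        pseudo_weight=float(header["pseudo_weight"]),
        n_training_cores=int(header["n_training_cores"]),
    )
    background = np.array([float(x) for x in header["background"].split("\t")])
    return AlleleModel(
        allele=header["allele"], pwm=pwm, background=background, calibration=calibration
    )


def save_models(models: dict[str, AlleleModel], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for allele, model in models.items():
        save_model(model, directory / f"{allele}.txt")


def load_models(directory) -> dict[str, AlleleModel]:
    models = {}
    for path in sorted(Path(directory).glob("*.txt")):
        model = load_model(path)
        models[model.allele] = model
    return models
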