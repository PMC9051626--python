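"""Reading, validation and filtering of immunopeptidomics inputs.

Covers the four external inputs of the pipeline: MS identification tables in
the MaxQuant ``msms.txt`` dialect, sample manifests with per-sample HLA-II
typing, a proteome in FASTA, and a phosphosite catalogue used as the
negative pool.  Also applies the PSM-level quality filters (identification
score, delta score, phospho localization probability, peptide length).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import (
    PARENT,
    PHOSPHORYLATABLE,
    SENTINEL,
    bracket_annotation,
    parse_bracket_annotation,
    parse_mod_string,
    to_mod_string,
)

__all__ = [
    "ModPeptide",
    "PSMRecord",
    "SampleManifest",
    "PhosphositeCatalogue",
    "Proteome",
    "ExtendedPeptide",
    "PSMReadResult",
    "SchemaError",
    "ModificationParseError",
    "read_psm_table",
    "write_psm_table",
    "filter_psms",
    "extend_peptide_context",
    "read_manifest",
    "write_manifest",
    "write_peptide_table",
    "read_peptide_table",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ModificationParseError(ValueError):
    """A modified-sequence string could not be parsed."""


@dataclass(frozen=True)
class ModPeptide:
    """A peptide with zero or more phosphorylated S/T/Y residues.

    ``sequence`` is the plain 20-letter sequence; ``phospho_positions`` are
    0-based indices into it.  Two peptides with equal sequence but different
    phosphosite placements are distinct objects: localization is the object
    of study.
    """

    sequence: str
    phospho_positions: frozenset[int] = frozenset()
    source_proteins: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "phospho_positions", frozenset(self.phospho_positions))
        object.__setattr__(self, "source_proteins", tuple(self.source_proteins))
        for i in self.phospho_positions:
            if not 0 <= i < len(self.sequence):
                raise ValueError(f"phospho position {i} outside peptide of length {len(self.sequence)}")
            if self.sequence[i] not in PHOSPHORYLATABLE:
                raise ValueError(
                    f"phospho position {i} points at {self.sequence[i]!r}, not S/T/Y"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_phospho(self) -> int:
        return len(self.phospho_positions)

    @property
    def phospho_residues(self) -> dict[int, str]:
        return {i: self.sequence[i] for i in sorted(self.phospho_positions)}

    @property
    def mod_sequence(self) -> str:
        """23-letter mod string with lowercase phospho residues."""
        return to_mod_string(self.sequence, self.phospho_positions)

    @property
    def key(self) -> tuple[str, frozenset[int]]:
        """Identity of the modified peptide: sequence plus phosphosite set."""
        return (self.sequence, self.phospho_positions)

    @classmethod
    def from_mod_string(cls, mod: str, source_proteins=()) -> "ModPeptide":
        seq, pos = parse_mod_string(mod)
        return cls(seq, pos, tuple(source_proteins))


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match with its identification-quality scores."""

    peptide: ModPeptide
    peptide_score: float
    delta_score: float
    localization_probs: tuple[float, ...] = ()
    sample_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "localization_probs", tuple(self.localization_probs))
        if self.delta_score < 0:
            raise ValueError("delta_score must be >= 0")
        for p in self.localization_probs:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"localization probability {p} outside [0, 1]")


_CAPTURES = ("DR-only", "pan-II-only", "both")


@dataclass(frozen=True)
class SampleManifest:
    """Per-sample HLA-II typing and capture-antibody type."""

    sample_id: str
    alleles: tuple[str, ...]
    capture: str = "both"

    def __post_init__(self):
        object.__setattr__(self, "alleles", tuple(self.alleles))
        if not self.alleles:
            raise ValueError(f"sample {self.sample_id}: allele list is empty")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"sample {self.sample_id}: duplicate alleles")
        if self.capture not in _CAPTURES:
            raise ValueError(f"capture must be one of {_CAPTURES}, got {self.capture!r}")


class Proteome:
    """A FASTA-backed protein sequence lookup."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = dict(sequences)

    @classmethod
    def from_fasta(cls, path) -> "Proteome":
        return cls({rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")})

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=pid, description="")
            for pid, seq in sorted(self.sequences.items())
        ]
        SeqIO.write(records, str(path), "fasta")

    def __getitem__(self, pid: str) -> str:
        return self.sequences[pid]

    def __contains__(self, pid: str) -> bool:
        return pid in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def find_occurrences(self, sequence: str, protein_ids=None) -> list[tuple[str, int]]:
        """All exact matches of ``sequence``, sorted by (protein id, start)."""
        hits: list[tuple[str, int]] = []
        ids = sorted(protein_ids) if protein_ids is not None else sorted(self.sequences)
        for pid in ids:
            prot = self.sequences.get(pid)
            if prot is None:
                continue
            start = prot.find(sequence)
            while start != -1:
                hits.append((pid, start))
                start = prot.find(sequence, start + 1)
        return hits


@dataclass(frozen=True)
class PhosphositeCatalogue:
    """Known phosphosites of a proteome: (protein id, 0-based position, residue)."""

    entries: tuple[tuple[str, int, str], ...]

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple((p, int(i), r) for p, i, r in self.entries))
        for pid, pos, res in self.entries:
            if res not in PHOSPHORYLATABLE:
                raise ValueError(f"catalogue residue {res!r} at {pid}:{pos} is not S/T/Y")

    def __len__(self) -> int:
        return len(self.entries)

    def validate_against(self, proteome: Proteome) -> None:
        for pid, pos, res in self.entries:
            prot = proteome[pid]
            if not 0 <= pos < len(prot) or prot[pos] != res:
                raise ValueError(
                    f"catalogue entry {pid}:{pos}:{res} does not match the proteome"
                )

    @classmethod
    def from_tsv(cls, path) -> "PhosphositeCatalogue":
        df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
        for col in ("protein_id", "position", "residue"):
            if col not in df.columns:
                raise SchemaError(f"phosphosite catalogue is missing required column {col!r}")
        return cls(tuple(zip(df["protein_id"], df["position"].astype(int), df["residue"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.entries, columns=["protein_id", "position", "residue"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# MaxQuant msms.txt dialect
# ---------------------------------------------------------------------------

#: Default column-name map for the MaxQuant msms.txt dialect.
MAXQUANT_COLUMNS = {
    "sample": "Raw file",
    "sequence": "Sequence",
    "modified_sequence": "Modified sequence",
    "score": "Score",
    "delta_score": "Delta score",
    "localization": "Phospho (STY) Probabilities",
    "proteins": "Proteins",
}

# Variable-modification tokens.  Phospho tokens mark the preceding residue;
# oxidation and N-terminal acetylation are parsed and then ignored, since
# only phosphorylation is analysed downstream.
_PHOSPHO_TOKENS = {"ph", "p", "phospho (sty)"}
_IGNORED_TOKENS = {"ox", "oxidation (m)", "ac", "acetyl (protein n-term)"}


def _parse_modified_sequence(text: str) -> tuple[str, frozenset[int]]:
    """Parse a MaxQuant modified sequence like ``_ASKDPS(ph)SR_``.

    Returns the plain sequence and the 0-based phospho positions.  Handles
    nested parentheses in long-form tokens such as ``(Phospho (STY))``.
    """
    text = text.strip().strip("_")
    seq: list[str] = []
    phospho: set[int] = set()
    i = 0
    while i < len(text):
        c = text[i]
        if c == "(":
            depth = 1
            j = i + 1
            while j < len(text) and depth:
                if text[j] == "(":
                    depth += 1
                elif text[j] == ")":
                    depth -= 1
                j += 1
            if depth:
                raise ModificationParseError(f"unbalanced parenthesis at column {i}: {text!r}")
            token = text[i + 1 : j - 1].strip().lower()
            if token in _PHOSPHO_TOKENS:
                if not seq:
                    raise ModificationParseError(f"phospho token precedes any residue: {text!r}")
                pos = len(seq) - 1
                if seq[pos] not in PHOSPHORYLATABLE:
                    raise ModificationParseError(
                        f"phospho on {seq[pos]!r} (position {pos}), not S/T/Y: {text!r}"
                    )
                phospho.add(pos)
            elif token not in _IGNORED_TOKENS:
                raise ModificationParseError(f"unknown modification token {token!r} in {text!r}")
            i = j
        elif c.isalpha():
            seq.append(c.upper())
            i += 1
        else:
            raise ModificationParseError(f"unexpected character {c!r} at column {i}")
    return "".join(seq), frozenset(phospho)


def _parse_probability_string(text: str) -> dict[int, float]:
    """Parse ``AS(0.988)KT(0.012)R`` into {position: probability}."""
    probs: dict[int, float] = {}
    pos = -1
    i = 0
    while i < len(text):
        c = text[i]
        if c == "(":
            j = text.find(")", i)
            if j == -1:
                raise ModificationParseError(f"unbalanced parenthesis in probabilities: {text!r}")
            if pos < 0:
                raise ModificationParseError(f"probability precedes any residue: {text!r}")
            probs[pos] = float(text[i + 1 : j])
            i = j + 1
        else:
            pos += 1
            i += 1
    return probs


def _format_probability_string(peptide: ModPeptide, probs) -> str:
    by_pos = dict(zip(sorted(peptide.phospho_positions), probs))
    out = []
    for i, c in enumerate(peptide.sequence):
        out.append(c)
        if i in by_pos:
            out.append(f"({by_pos[i]:g})")
    return "".join(out)


@dataclass
class PSMReadResult:
    """Parsed PSMs plus a report of rows that could not be parsed."""

    records: list[PSMRecord]
    n_rows: int
    skipped: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.skipped)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def read_psm_table(path, columns: dict[str, str] | None = None) -> PSMReadResult:
    """Read a tab-separated identification table in the MaxQuant msms.txt dialect.

    ``columns`` overrides the default column-name map.  A missing required
    column is a fatal :class:`SchemaError`; a row with unparseable
    modification syntax is excluded with a warning and counted in the
    returned report, never silently dropped.
    """
    colmap = dict(MAXQUANT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key, col in colmap.items():
        if col not in df.columns:
            raise SchemaError(f"identification table is missing required column {col!r} ({key})")
    records: list[PSMRecord] = []
    skipped: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            seq, phospho = _parse_modified_sequence(row[colmap["modified_sequence"]])
            plain = row[colmap["sequence"]].strip().upper()
            if plain and plain != seq:
                raise ModificationParseError(
                    f"sequence column {plain!r} disagrees with modified sequence {seq!r}"
                )
            if phospho:
                probs_by_pos = _parse_probability_string(row[colmap["localization"]])
                try:
                    probs = tuple(probs_by_pos[i] for i in sorted(phospho))
                except KeyError as exc:
                    raise ModificationParseError(
                        f"no localization probability for phosphosite at position {exc.args[0]}"
                    ) from None
            else:
                probs = ()
            proteins = tuple(p for p in row[colmap["proteins"]].split(";") if p)
            peptide = ModPeptide(seq, phospho, proteins)
            records.append(
                PSMRecord(
                    peptide=peptide,
                    peptide_score=float(row[colmap["score"]]),
                    delta_score=float(row[colmap["delta_score"]]),
                    localization_probs=probs,
                    sample_id=row[colmap["sample"]],
                )
            )
        except (ModificationParseError, ValueError) as exc:
            warnings.warn(f"row {idx}: {exc}", stacklevel=2)
            skipped.append((int(idx), str(exc)))
    return PSMReadResult(records=records, n_rows=len(df), skipped=skipped)


def write_psm_table(records, path, columns: dict[str, str] | None = None) -> None:
    """Write PSMs as a tab-separated table in the MaxQuant msms.txt dialect."""
    colmap = dict(MAXQUANT_COLUMNS)
    if columns:
        colmap.update(columns)
    rows = []
    for rec in records:
        pep = rec.peptide
        mods = "".join(
            pep.sequence[i] + "(ph)" if i in pep.phospho_positions else pep.sequence[i]
            for i in range(len(pep))
        )
        rows.append(
            {
                colmap["sample"]: rec.sample_id,
                colmap["sequence"]: pep.sequence,
                colmap["modified_sequence"]: f"_{mods}_",
                colmap["score"]: f"{rec.peptide_score:.8g}",
                colmap["delta_score"]: f"{rec.delta_score:.8g}",
                colmap["localization"]: _format_probability_string(pep, rec.localization_probs),
                colmap["proteins"]: ";".join(pep.source_proteins),
            }
        )
    cols = [colmap[k] for k in MAXQUANT_COLUMNS]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def filter_psms(
    records,
    min_score: float = 40.0,
    min_delta: float = 10.0,
    min_locprob: float = 0.75,
    len_range: tuple[int, int] = (12, 25),
) -> list[PSMRecord]:
    """Apply the PSM quality filters.

    Keeps records with identification score >= ``min_score``, delta score >=
    ``min_delta``, every phospho localization probability strictly >
    ``min_locprob``, and peptide length within ``len_range`` (inclusive).
    Pure filter: order preserved, idempotent.
    """
    lo, hi = len_range
    return [
        r
        for r in records
        if r.peptide_score >= min_score
        and r.delta_score >= min_delta
        and all(p > min_locprob for p in r.localization_probs)
        and lo <= len(r.peptide) <= hi
    ]


# ---------------------------------------------------------------------------
# Context extension
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtendedPeptide:
    """A peptide with ``flank`` residues of protein context on each side.

    ``text`` is a mod string of length ``len(peptide) + 2*flank``; positions
    outside the source protein are the sentinel ``-``.  The peptide proper
    starts at ``offset == flank``.
    """

    peptide: ModPeptide
    text: str
    offset: int
    protein_id: str | None = None
    start: int | None = None

    @property
    def matched(self) -> bool:
        return self.protein_id is not None


def extend_peptide_context(peptide: ModPeptide, proteome: Proteome, flank: int) -> ExtendedPeptide:
    """Extend a peptide N- and C-terminally with up to ``flank`` protein residues.

    The source protein is located by exact substring match, preferring the
    peptide's recorded source proteins; among multiple matches the
    lexicographically smallest protein id (then smallest start) wins.  At a
    protein terminus the missing context is padded with the sentinel symbol.
    A peptide with no exact match is flagged (warning) and returned
    unextended with full sentinel padding.
    """
    hits = []
    if peptide.source_proteins:
        hits = proteome.find_occurrences(
            peptide.sequence, [p for p in peptide.source_proteins if p in proteome]
        )
    if not hits:
        hits = proteome.find_occurrences(peptide.sequence)
    if not hits:
        warnings.warn(
            f"peptide {peptide.sequence} has no exact match in the proteome; "
            "using sentinel padding only",
            stacklevel=2,
        )
        return ExtendedPeptide(
            peptide=peptide,
            text=SENTINEL * flank + peptide.mod_sequence + SENTINEL * flank,
            offset=flank,
        )
    pid, start = hits[0]
    prot = proteome[pid]
    left = prot[max(0, start - flank) : start]
    right = prot[start + len(peptide) : start + len(peptide) + flank]
    text = (
        SENTINEL * (flank - len(left))
        + left
        + peptide.mod_sequence
        + right
        + SENTINEL * (flank - len(right))
    )
    return ExtendedPeptide(peptide=peptide, text=text, offset=flank, protein_id=pid, start=start)


# ---------------------------------------------------------------------------
# Manifests and peptide tables
# ---------------------------------------------------------------------------


def read_manifest(path) -> dict[str, SampleManifest]:
    """Read a tab-separated sample manifest (sample_id, alleles ;-separated, capture)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sample_id", "alleles", "capture"):
        if col not in df.columns:
            raise SchemaError(f"manifest is missing required column {col!r}")
    out = {}
    for _, row in df.iterrows():
        m = SampleManifest(
            sample_id=row["sample_id"],
            alleles=tuple(a for a in row["alleles"].split(";") if a),
            capture=row["capture"],
        )
        out[m.sample_id] = m
    return out


def write_manifest(manifests, path) -> None:
    rows = [
        {"sample_id": m.sample_id, "alleles": ";".join(m.alleles), "capture": m.capture}
        for m in (manifests.values() if isinstance(manifests, dict) else manifests)
    ]
    pd.DataFrame(rows, columns=["sample_id", "alleles", "capture"]).to_csv(
        path, sep="\t", index=False
    )


def write_peptide_table(records, path) -> None:
    """Write filtered PSMs with explicit phospho annotation.

    Columns: sample_id, annotated peptide (``ASKDPS[p]SR`` style), 0-based
    phosphosite list, scores and source proteins.
    """
    rows = []
    for rec in records:
        pep = rec.peptide
        rows.append(
            {
                "sample_id": rec.sample_id,
                "peptide": bracket_annotation(pep.mod_sequence),
                "phospho_sites": ";".join(str(i) for i in sorted(pep.phospho_positions)),
                "peptide_score": f"{rec.peptide_score:.8g}",
                "delta_score": f"{rec.delta_score:.8g}",
                "localization_probs": ";".join(f"{p:g}" for p in rec.localization_probs),
                "proteins": ";".join(pep.source_proteins),
            }
        )
    cols = [
        "sample_id",
        "peptide",
        "phospho_sites",
        "peptide_score",
        "delta_score",
        "localization_probs",
        "proteins",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_peptide_table(path) -> list[PSMRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        mod = parse_bracket_annotation(row["peptide"])
        pep = ModPeptide.from_mod_string(
            mod, tuple(p for p in row.get("proteins", "").split(";") if p)
        )
        probs = tuple(float(p) for p in row["localization_probs"].split(";") if p)
        records.append(
            PSMRecord(
                peptide=pep,
                peptide_score=float(row["peptide_score"]),
                delta_score=float(row["delta_score"]),
                localization_probs=probs,
                sample_id=row["sample_id"],
            )
        )
    return records
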