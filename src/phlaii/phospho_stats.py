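"""Positional statistics of phosphosites and kinase-motif enrichment.

Positional analyses classify each phosphosite of an assigned ligand as
binding-core (within the 9-mer at the predicted offset) or flanking (PFR),
summarize terminal phosphosites (first three / last three peptide
positions), and give the per-core-position (P1..P9) phosphosite
distribution overall and per allele.

Kinase-motif analyses scan short substrate patterns (bracket grammar, e.g.
``[pS/pT]P`` or ``RXX[pS/pT]``) over context-extended ligands, normalize
match counts by the number of anchor-type sites, and test enrichment of
each motif in phosphorylated vs unmodified ligands with a one-sided
Fisher's exact test, with the human phosphoproteome as the reference
stratum.  A source-gene overlap odds ratio controls for protein-of-origin
bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .alphabet import DISPLAY, PARENT, PHOSPHORYLATABLE, SENTINEL
from .peptidome_io import ExtendedPeptide, PhosphositeCatalogue, Proteome
from .pwm import CORE_LENGTH

__all__ = [
    "RegionCounts",
    "TerminalDistribution",
    "CorePositionDistribution",
    "KinaseMotif",
    "EnrichmentResult",
    "OddsRatioResult",
    "phospho_core_vs_pfr",
    "terminal_phospho_distribution",
    "core_position_distribution",
    "parse_kinase_motif",
    "scan_kinase_motif",
    "kinase_enrichment",
    "extend_catalogue_sites",
    "source_gene_overlap_odds_ratio",
]


# ---------------------------------------------------------------------------
# Positional statistics (core vs PFR, terminal positions, P1..P9)
# ---------------------------------------------------------------------------


@dataclass
class RegionCounts:
    """Phosphosite and all-residue counts in binding core vs PFRs."""

    phospho_core: int
    phospho_pfr: int
    total_core: int
    total_pfr: int

    @property
    def phospho_core_fraction(self) -> float:
        n = self.phospho_core + self.phospho_pfr
        return self.phospho_core / n if n else float("nan")

    @property
    def total_core_fraction(self) -> float:
        n = self.total_core + self.total_pfr
        return self.total_core / n if n else float("nan")


def phospho_core_vs_pfr(interactions) -> RegionCounts:
    """Classify phosphosites and all residues by core membership.

    The core interval is ``[core_offset, core_offset + 9)``; everything
    else is PFR.  Both the phosphosite and the all-residue denominators are
    reported so the phosphosite distribution can be compared with the
    residue distribution.
    """
    counts = RegionCounts(0, 0, 0, 0)
    for x in interactions:
        lo, hi = x.core_offset, x.core_offset + CORE_LENGTH
        for i in range(len(x.peptide)):
            in_core = lo <= i < hi
            if in_core:
                counts.total_core += 1
            else:
                counts.total_pfr += 1
            if i in x.peptide.phospho_positions:
                if in_core:
                    counts.phospho_core += 1
                else:
                    counts.phospho_pfr += 1
    return counts


@dataclass
class TerminalDistribution:
    """Phosphosites within the first three / last three peptide positions.

    Counted both per site and per peptide (a peptide with terminal sites at
    both ends contributes to both ends; whether the published split counts
    sites or peptides is ambiguous, so both are reported).  N-terminal
    positions are reported 1-based (index 0 -> position 1).
    """

    n_term_sites: int
    c_term_sites: int
    n_term_peptides: int
    c_term_peptides: int
    nterm_position_counts: np.ndarray  # sites at N-terminal positions 1..3

    @property
    def c_term_site_fraction(self) -> float:
        n = self.n_term_sites + self.c_term_sites
        return self.c_term_sites / n if n else float("nan")

    @property
    def nterm_position_fractions(self) -> np.ndarray:
        total = self.nterm_position_counts.sum()
        return self.nterm_position_counts / total if total else np.full(3, np.nan)


def terminal_phospho_distribution(peptides) -> TerminalDistribution:
    """Terminal phosphosite counts over (unique) peptides.

    A phosphosite is N-terminal if its 0-based index is < 3 and C-terminal
    if its index is >= length - 3.
    """
    n_sites = c_sites = n_peps = c_peps = 0
    nterm_pos = np.zeros(3, dtype=int)
    for pep in peptides:
        has_n = has_c = False
        for i in sorted(pep.phospho_positions):
            if i < 3:
                n_sites += 1
                nterm_pos[i] += 1
                has_n = True
            if i >= len(pep) - 3:
                c_sites += 1
                has_c = True
        n_peps += has_n
        c_peps += has_c
    return TerminalDistribution(
        n_term_sites=n_sites,
        c_term_sites=c_sites,
        n_term_peptides=n_peps,
        c_term_peptides=c_peps,
        nterm_position_counts=nterm_pos,
    )


@dataclass
class CorePositionDistribution:
    """Distribution of in-core phosphosites over P1..P9."""

    counts: np.ndarray  # shape (9,)
    per_allele: dict[str, np.ndarray]  # allele -> frequency vector (9,)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def core_position_distribution(interactions) -> CorePositionDistribution:
    """Per-core-position phosphosite frequencies, overall and per allele.

    Only peptides with at least one phosphosite inside the binding core
    contribute; each in-core phosphosite of a multiply-phosphorylated
    peptide counts once, so the frequencies sum to 1 over P1..P9.
    """
    counts = np.zeros(CORE_LENGTH, dtype=int)
    allele_counts: dict[str, np.ndarray] = {}
    for x in interactions:
        in_core = [
            i - x.core_offset
            for i in x.peptide.phospho_positions
            if x.core_offset <= i < x.core_offset + CORE_LENGTH
        ]
        if not in_core:
            continue
        vec = allele_counts.setdefault(x.allele, np.zeros(CORE_LENGTH, dtype=int))
        for p in in_core:
            counts[p] += 1
            vec[p] += 1
    per_allele = {a: v / v.sum() for a, v in sorted(allele_counts.items())}
    return CorePositionDistribution(counts=counts, per_allele=per_allele)


# ---------------------------------------------------------------------------
# Kinase motifs
# ---------------------------------------------------------------------------

_PHOSPHO_TOKENS = {"pS", "pT", "pY"}


class MotifSyntaxError(ValueError):
    """A kinase-motif pattern string is malformed."""


@dataclass(frozen=True)
class KinaseMotif:
    """A kinase substrate pattern anchored at a phosphosite.

    ``positions`` holds one residue-set per pattern position (``None`` for
    the wildcard ``X``); exactly one position — the anchor — contains
    phospho tokens.
    """

    positions: tuple[frozenset[str] | None, ...]
    anchor_index: int
    name: str = ""

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def anchor_parents(self) -> frozenset[str]:
        """Unmodified residue types of the anchor set, e.g. {S, T} for [pS/pT]."""
        return frozenset(
            tok[1] for tok in self.positions[self.anchor_index] if tok in _PHOSPHO_TOKENS
        )

    @property
    def text(self) -> str:
        """Canonical pattern text; round-trips through the parser."""
        parts = []
        for spec in self.positions:
            if spec is None:
                parts.append("X")
                continue
            plain = sorted(t for t in spec if t not in _PHOSPHO_TOKENS)
            phos = sorted(t for t in spec if t in _PHOSPHO_TOKENS)
            tokens = phos + plain
            parts.append(tokens[0] if len(tokens) == 1 else "[" + "/".join(tokens) + "]")
        return "".join(parts)


def parse_kinase_motif(pattern_text: str, name: str = "") -> KinaseMotif:
    """Parse a bracket-grammar kinase motif such as ``RXX[pS/pT]``.

    Tokens are single residues, phospho residues ``pS``/``pT``/``pY``,
    bracketed alternatives ``[D/E]``, and the wildcard ``X``.  Exactly one
    position must contain phospho tokens (the anchor).
    """
    text = pattern_text.strip()
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "[":
            j = text.find("]", i)
            if j == -1:
                raise MotifSyntaxError(f"unclosed bracket at column {i}: {text!r}")
            tokens = [t.strip() for t in text[i + 1 : j].split("/")]
            spec = set()
            for tok in tokens:
                if tok in _PHOSPHO_TOKENS or (len(tok) == 1 and tok.isalpha() and tok != "X"):
                    spec.add(tok)
                else:
                    raise MotifSyntaxError(f"bad token {tok!r} at column {i}: {text!r}")
            positions.append(frozenset(spec))
            i = j + 1
        elif c == "X":
            positions.append(None)
            i += 1
        elif c == "p" and i + 1 < len(text) and text[i + 1] in PHOSPHORYLATABLE:
            positions.append(frozenset({text[i : i + 2]}))
            i += 2
        elif c.isalpha():
            positions.append(frozenset({c.upper()}))
            i += 1
        else:
            raise MotifSyntaxError(f"unexpected character {c!r} at column {i}: {text!r}")
    anchors = [
        k
        for k, spec in enumerate(positions)
        if spec is not None and spec & _PHOSPHO_TOKENS
    ]
    if len(anchors) != 1:
        raise MotifSyntaxError(
            f"pattern {text!r} must contain exactly one phospho anchor, found {len(anchors)}"
        )
    return KinaseMotif(positions=tuple(positions), anchor_index=anchors[0], name=name)


def read_kinase_motifs(path) -> list[KinaseMotif]:
    """Read a plain-text motif list: one pattern per line, optional name after a tab."""
    motifs = []
    for line in open(path):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pattern, _, name = line.partition("\t")
        motifs.append(parse_kinase_motif(pattern, name=name.strip()))
    return motifs


def _symbol_matches(ch: str, spec: frozenset[str] | None, phospho_aware: bool) -> bool:
    if ch == SENTINEL:
        return False  # the sentinel matches no motif position, wildcard included
    if spec is None:
        return True
    if not phospho_aware:
        # unmodified stratum: phospho tokens stand for their parent residues
        stripped = {t[1] if t in _PHOSPHO_TOKENS else t for t in spec}
        return PARENT.get(ch, ch) in stripped
    if ch in PARENT:  # phosphorylated residue matches only phospho tokens
        return DISPLAY[ch] in spec
    return ch in spec


def _anchor_sites(extended: ExtendedPeptide, parents: frozenset[str], phospho_aware: bool):
    """Positions (in extended text) of anchor-type sites within the peptide proper."""
    pep = extended.peptide
    sites = []
    for i in range(len(pep)):
        res = pep.sequence[i]
        if res not in parents:
            continue
        is_phos = i in pep.phospho_positions
        if phospho_aware == is_phos:
            sites.append(extended.offset + i)
    return sites


def scan_kinase_motif(
    motif: KinaseMotif, extended_peptides, phospho_aware: bool = True
) -> tuple[int, int]:
    """Count motif matches and anchor-type sites over extended peptides.

    The denominator is every site whose residue type matches the anchor's
    parent set (phosphosites when ``phospho_aware``, unmodified S/T/Y
    otherwise); the count is the subset whose surrounding window matches
    the full pattern.  A window that runs into sentinel padding is no
    match but still counts in the denominator.
    """
    matches, sites = _scan_sites(motif, extended_peptides, phospho_aware)
    return len(matches), sites


def motif_match_sites(
    motif: KinaseMotif, extended_peptides, phospho_aware: bool = True
) -> list[tuple[int, int]]:
    """(peptide index, site position) of every matching anchor site."""
    matched, _ = _scan_sites(motif, extended_peptides, phospho_aware)
    return matched


def _scan_sites(motif, extended_peptides, phospho_aware):
    parents = motif.anchor_parents
    n_sites = 0
    matched: list[tuple[int, int]] = []
    for k, ext in enumerate(extended_peptides):
        for site in _anchor_sites(ext, parents, phospho_aware):
            n_sites += 1
            start = site - motif.anchor_index
            if start < 0 or start + len(motif) > len(ext.text):
                continue
            window = ext.text[start : start + len(motif)]
            if all(
                _symbol_matches(window[i], motif.positions[i], phospho_aware)
                for i in range(len(motif))
            ):
                matched.append((k, site))
    return matched, n_sites


@dataclass
class EnrichmentResult:
    """Counts, frequencies and the one-sided Fisher p-value for one motif."""

    motif: KinaseMotif
    count_phos: int
    denom_phos: int
    count_unmod: int
    denom_unmod: int
    count_phosphoproteome: int
    denom_phosphoproteome: int
    p_value: float
    flagged: bool = False  # zero denominator in a stratum: no test performed

    def _freq(self, count: int, denom: int) -> float:
        return count / denom if denom else float("nan")

    @property
    def freq_phos(self) -> float:
        return self._freq(self.count_phos, self.denom_phos)

    @property
    def freq_unmod(self) -> float:
        return self._freq(self.count_unmod, self.denom_unmod)

    @property
    def freq_phosphoproteome(self) -> float:
        return self._freq(self.count_phosphoproteome, self.denom_phosphoproteome)


def fisher_one_sided(count_a: int, denom_a: int, count_b: int, denom_b: int) -> float:
    """One-sided Fisher's exact p for enrichment of the event in stratum a."""
    table = [[count_a, denom_a - count_a], [count_b, denom_b - count_b]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def kinase_enrichment(
    motifs,
    phos_extended,
    unmod_extended,
    phosphoproteome_extended,
    alpha: float = 0.05,
    nonredundant: bool = True,
) -> list[EnrichmentResult]:
    """Per-motif enrichment of phosphorylated vs unmodified HLA-II ligands.

    Each motif is scanned phospho-aware on the phosphorylated ligands and
    the phosphoproteome sites and modification-blind on the unmodified
    ligands; the one-sided Fisher test asks whether the match frequency is
    higher in the phospho stratum than among unmodified ligands.  With
    ``nonredundant``, a motif whose phospho-stratum match set is contained
    in that of a shorter retained motif is dropped.  Results are sorted by
    descending phosphoproteome frequency.
    """
    scanned = []
    for motif in motifs:
        phos_matches, denom_phos = _scan_sites(motif, phos_extended, phospho_aware=True)
        count_unmod, denom_unmod = scan_kinase_motif(motif, unmod_extended, phospho_aware=False)
        count_pp, denom_pp = scan_kinase_motif(
            motif, phosphoproteome_extended, phospho_aware=True
        )
        flagged = denom_phos == 0 or denom_unmod == 0
        p = (
            float("nan")
            if flagged
            else fisher_one_sided(len(phos_matches), denom_phos, count_unmod, denom_unmod)
        )
        scanned.append(
            (
                EnrichmentResult(
                    motif=motif,
                    count_phos=len(phos_matches),
                    denom_phos=denom_phos,
                    count_unmod=count_unmod,
                    denom_unmod=denom_unmod,
                    count_phosphoproteome=count_pp,
                    denom_phosphoproteome=denom_pp,
                    p_value=p,
                    flagged=flagged,
                ),
                frozenset(phos_matches),
            )
        )
    if nonredundant:
        retained: list[tuple[EnrichmentResult, frozenset]] = []
        for res, matchset in sorted(scanned, key=lambda t: len(t[0].motif)):
            if any(
                len(other.motif) < len(res.motif) and matchset <= other_set
                for other, other_set in retained
            ):
                continue
            retained.append((res, matchset))
        scanned = retained
    results = [res for res, _ in scanned]
    results.sort(key=lambda r: (-(r.freq_phosphoproteome if r.denom_phosphoproteome else -1)))
    return results


def extend_catalogue_sites(
    catalogue: PhosphositeCatalogue, proteome: Proteome, flank: int
) -> list[ExtendedPeptide]:
    """Represent each catalogue phosphosite as a 1-residue extended peptide.

    Gives the phosphoproteome stratum the same scanning interface as
    context-extended ligands: the site residue (phosphorylated) with
    ``flank`` residues of protein context on each side.
    """
    from .peptidome_io import ModPeptide

    out = []
    for pid, pos, res in catalogue.entries:
        prot = proteome[pid]
        left = prot[max(0, pos - flank) : pos]
        right = prot[pos + 1 : pos + 1 + flank]
        text = (
            SENTINEL * (flank - len(left))
            + left
            + res.lower()
            + right
            + SENTINEL * (flank - len(right))
        )
        pep = ModPeptide(res, frozenset({0}), (pid,))
        out.append(
            ExtendedPeptide(peptide=pep, text=text, offset=flank, protein_id=pid, start=pos)
        )
    return out


@dataclass
class OddsRatioResult:
    odds_ratio: float
    table: np.ndarray  # 2x2 counts over the universe partition (uncorrected)
    corrected: bool  # Haldane +0.5 applied because of a zero cell


def source_gene_overlap_odds_ratio(
    hla_ligand_genes: set, motif_phosphosite_genes: set, universe: set
) -> OddsRatioResult:
    """Odds ratio of the overlap between two gene sets within a universe.

    Partitions the universe by membership in each set; the odds ratio is
    (a*d)/(b*c) with a Haldane correction (+0.5 on every cell) applied and
    flagged iff any cell is zero.  An odds ratio near 1 means the motif-
    bearing source genes are neither enriched nor depleted among ligand
    source genes.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("gene universe is empty")
    lig = set(hla_ligand_genes)
    mot = set(motif_phosphosite_genes)
    if not lig <= universe or not mot <= universe:
        raise ValueError("both gene sets must be subsets of the universe")
    a = len(lig & mot)
    b = len(lig - mot)
    c = len(mot - lig)
    d = len(universe - lig - mot)
    table = np.array([[a, b], [c, d]])
    corrected = (table == 0).any()
    t = table + 0.5 if corrected else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return OddsRatioResult(odds_ratio=float(odds), table=table, corrected=bool(corrected))
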