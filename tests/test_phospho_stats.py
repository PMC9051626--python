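"""Positional phosphosite statistics and kinase-motif machinery."""

import math
import re

import numpy as np
import pytest

from phlaii.assignment import Interaction
from phlaii.peptidome_io import ExtendedPeptide, ModPeptide
from phlaii.phospho_stats import (
    MotifSyntaxError,
    core_position_distribution,
    extend_catalogue_sites,
    fisher_one_sided,
    kinase_enrichment,
    parse_kinase_motif,
    phospho_core_vs_pfr,
    scan_kinase_motif,
    source_gene_overlap_odds_ratio,
    terminal_phospho_distribution,
)


def _inter(mod, offset, allele="A", sample="s"):
    pep = ModPeptide.from_mod_string(mod)
    return Interaction(sample, allele, pep, offset, mod[offset : offset + 9], 0.0, 1.0)


class TestCoreVsPfr:
    def test_site_inside_core(self):
        x = _inter("ACDEFsHIKLMNPQR", 3)  # 15-mer, core [3, 12), pS at 5
        rc = phospho_core_vs_pfr([x])
        assert (rc.phospho_core, rc.phospho_pfr) == (1, 0)

    def test_site_in_pfr(self):
        x = _inter("ACsEFGHIKLMNPQR", 3)  # pS at 2, core starts at 3
        rc = phospho_core_vs_pfr([x])
        assert (rc.phospho_core, rc.phospho_pfr) == (0, 1)

    def test_matches_brute_force_residue_loop(self, world):
        from phlaii.pipeline import interactions_from_truth

        inter = interactions_from_truth(world, kinds=("ligand_phos",))[:100]
        rc = phospho_core_vs_pfr(inter)
        pc = pp = tc = tp = 0
        for x in inter:
            for i in range(len(x.peptide)):
                core = x.core_offset <= i < x.core_offset + 9
                tc += core
                tp += not core
                if i in x.peptide.phospho_positions:
                    pc += core
                    pp += not core
        assert (rc.phospho_core, rc.phospho_pfr) == (pc, pp)
        assert (rc.total_core, rc.total_pfr) == (tc, tp)


class TestTerminalDistribution:
    def test_nterm_position_three(self):
        pep = ModPeptide.from_mod_string("ACsEFGHIKLMNPQ")  # pS index 2 of a 14-mer
        td = terminal_phospho_distribution([pep])
        assert td.n_term_sites == 1 and td.c_term_sites == 0
        assert list(td.nterm_position_counts) == [0, 0, 1]

    def test_interior_site_is_neither(self):
        pep = ModPeptide.from_mod_string("ACDEFGHsKLMNPQ")  # index 7 of 14
        td = terminal_phospho_distribution([pep])
        assert td.n_term_sites == 0 and td.c_term_sites == 0

    def test_both_ends_counted_for_both(self):
        pep = ModPeptide.from_mod_string("AsDEFGHIKLMNsQ")
        td = terminal_phospho_distribution([pep])
        assert td.n_term_peptides == 1 and td.c_term_peptides == 1

    def test_planted_terminal_split_recovered(self, world):
        peps = [
            ModPeptide.from_mod_string(t.mod_sequence)
            for t in world.truth
            if t.kind == "ligand_phos"
        ]
        td = terminal_phospho_distribution(peps)
        n = td.n_term_sites + td.c_term_sites
        assert n >= 200
        # C-terminal bias planted at 0.63; flank availability damps it a little
        assert abs(td.c_term_site_fraction - world.config.cterm_prob) < 0.08
        assert td.c_term_site_fraction > 0.5
        # third N-terminal position favoured, as planted
        assert int(np.argmax(td.nterm_position_counts)) == 2


class TestCorePositionDistribution:
    def test_single_site_at_p5(self):
        x = _inter("ACDEFGHIsLMNPQR", 4)  # core [4,13), site index 8 -> P5
        cpd = core_position_distribution([x])
        assert cpd.frequencies[4] == pytest.approx(1.0)
        assert cpd.counts.sum() == 1

    def test_multiple_in_core_sites_each_count(self):
        x = _inter("ACDEsGHItLMNPQR", 3)  # sites 4 and 8 -> P2 and P6
        cpd = core_position_distribution([x])
        assert cpd.counts[1] == 1 and cpd.counts[5] == 1
        assert cpd.frequencies.sum() == pytest.approx(1.0)

    def test_planted_p5_peak_and_p1_depletion(self, world):
        from phlaii.pipeline import interactions_from_truth

        inter = interactions_from_truth(world, kinds=("ligand_phos",))
        cpd = core_position_distribution(inter)
        freqs = cpd.frequencies
        assert int(np.argmax(freqs)) == 4  # P5 preference
        assert freqs[0] < 0.5 * freqs.mean()  # P1 depleted
        assert freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_per_allele_vectors_normalized(self, world):
        from phlaii.pipeline import interactions_from_truth

        inter = interactions_from_truth(world, kinds=("ligand_phos",))
        cpd = core_position_distribution(inter)
        assert set(cpd.per_allele) == set(world.alleles)
        for v in cpd.per_allele.values():
            assert v.sum() == pytest.approx(1.0)


class TestKinaseMotifParsing:
    def test_proline_directed(self):
        m = parse_kinase_motif("[pS/pT]P")
        assert len(m) == 2 and m.anchor_index == 0
        assert m.anchor_parents == frozenset({"S", "T"})
        assert m.text == "[pS/pT]P"

    def test_basophilic_with_wildcards(self):
        m = parse_kinase_motif("RXX[pS/pT]")
        assert len(m) == 4 and m.anchor_index == 3
        assert m.positions[1] is None and m.positions[2] is None

    def test_no_anchor_is_an_error(self):
        with pytest.raises(MotifSyntaxError, match="exactly one"):
            parse_kinase_motif("XX")

    def test_two_anchors_is_an_error(self):
        with pytest.raises(MotifSyntaxError, match="exactly one"):
            parse_kinase_motif("pSpT")

    def test_unclosed_bracket_reports_column(self):
        with pytest.raises(MotifSyntaxError, match="column 1"):
            parse_kinase_motif("R[pS/pT")

    @pytest.mark.parametrize("text", ["[pS/pT]P", "RXX[pS/pT]", "[pS/pT]XX[D/E]", "pYXXM"])
    def test_round_trip(self, text):
        assert parse_kinase_motif(text).text == text


def _ext(mod_center, left="AAAA", right="GGGG"):
    """Extended peptide whose peptide proper is ``mod_center``."""
    pep = ModPeptide.from_mod_string(mod_center)
    return ExtendedPeptide(
        peptide=pep, text=left + mod_center + right, offset=len(left), protein_id="P", start=0
    )


class TestScanKinaseMotif:
    def test_proline_after_phosphosite_matches(self):
        motif = parse_kinase_motif("[pS/pT]P")
        count, denom = scan_kinase_motif(motif, [_ext("AsPGLMKWIHDR")])
        assert (count, denom) == (1, 1)

    def test_no_proline_counts_denominator_only(self):
        motif = parse_kinase_motif("[pS/pT]P")
        count, denom = scan_kinase_motif(motif, [_ext("AsGGLMKWIHDR")])
        assert (count, denom) == (0, 1)

    def test_sentinel_window_skipped_but_in_denominator(self):
        motif = parse_kinase_motif("RXX[pS/pT]")
        ext = _ext("sPGGLMKWIHDR", left="----", right="GGGG")
        count, denom = scan_kinase_motif(motif, [ext])
        assert (count, denom) == (0, 1)

    def test_unmodified_stratum_uses_parent_residues(self):
        motif = parse_kinase_motif("[pS/pT]P")
        count, denom = scan_kinase_motif(
            motif, [_ext("ASPGLMKWIHDR")], phospho_aware=False
        )
        assert (count, denom) == (1, 1)

    def test_agrees_with_regex_oracle(self, rng):
        # 200 synthetic sites vs 5 motifs against an independent regex scan
        motifs = {
            "[pS/pT]P": r"[st]P",
            "RXX[pS/pT]": r"R..[st]",
            "[pS/pT]XX[D/E]": r"[st]..[DE]",
            "R[pS/pT]": r"R[st]",
            "[pS/pT]Q": r"[st]Q",
        }
        aas = "ACDEFGHIKLMNPQRSTVWY"
        exts = []
        for _ in range(200):
            seq = "".join(aas[i] for i in rng.integers(0, 20, 13))
            sty = [i for i, c in enumerate(seq) if c in "STY"]
            if not sty:
                continue
            site = sty[int(rng.integers(len(sty)))]
            mod = seq[:site] + seq[site].lower() + seq[site + 1 :]
            left = "".join(aas[i] for i in rng.integers(0, 20, 3))
            right = "".join(aas[i] for i in rng.integers(0, 20, 3))
            exts.append(_ext(mod, left, right))
        assert len(exts) >= 100
        for text, pattern in motifs.items():
            motif = parse_kinase_motif(text)
            count, denom = scan_kinase_motif(motif, exts)
            # oracle: regex over each extended text, anchored at the phosphosite
            expect_count = expect_denom = 0
            parents = {"[pS/pT]P": "ST", "RXX[pS/pT]": "ST", "[pS/pT]XX[D/E]": "ST",
                       "R[pS/pT]": "ST", "[pS/pT]Q": "ST"}[text]
            for ext in exts:
                for i, c in enumerate(ext.peptide.sequence):
                    if i in ext.peptide.phospho_positions and c in parents:
                        expect_denom += 1
                        pos = ext.offset + i
                        window = ext.text[pos - motif.anchor_index :][: len(motif)]
                        if re.fullmatch(pattern, window):
                            expect_count += 1
            assert (count, denom) == (expect_count, expect_denom)


class TestFisher:
    def test_hand_enumerated_table(self):
        # one-sided tail of the hypergeometric for [[3,1],[1,3]]
        assert fisher_one_sided(3, 4, 1, 4) == pytest.approx(17 / 70)

    def test_no_enrichment_direction_gives_large_p(self):
        assert fisher_one_sided(5, 50, 5, 50) >= 0.5

    def test_matches_tail_enumeration_on_small_tables(self, rng):
        # random 2x2 tables with n <= 30 against explicit tail enumeration
        for _ in range(200):
            n = int(rng.integers(2, 31))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n - a + 1))
            c = int(rng.integers(0, n - a - b + 1))
            d = n - a - b - c
            p = fisher_one_sided(a, a + b, c, c + d)
            # hypergeometric tail: draws of size a+b from (a+c) successes
            K, N, k = a + c, n, a + b
            tail = sum(
                math.comb(K, x) * math.comb(N - K, k - x) / math.comb(N, k)
                for x in range(a, min(K, k) + 1)
            )
            assert p == pytest.approx(tail, rel=1e-9, abs=1e-12)


class TestEnrichment:
    def test_zero_denominator_is_flagged_not_tested(self):
        motif = parse_kinase_motif("[pS/pT]P")
        res = kinase_enrichment([motif], [], [_ext("ASPGLMKWIHDR")], [])
        assert res[0].flagged and np.isnan(res[0].p_value)

    def test_counts_and_frequencies_consistent(self, world, discovery):
        from phlaii.assignment import unique_peptides
        from phlaii.peptidome_io import extend_peptide_context

        motifs = [parse_kinase_motif(t) for t in ("[pS/pT]P", "RXX[pS/pT]")]
        inter = discovery.outcome.interactions
        phos = unique_peptides([x for x in inter if x.peptide.n_phospho])[:120]
        unmod = unique_peptides([x for x in inter if not x.peptide.n_phospho])[:120]
        pe = [extend_peptide_context(p, world.proteome, 3) for p in phos]
        ue = [extend_peptide_context(p, world.proteome, 3) for p in unmod]
        ce = extend_catalogue_sites(world.catalogue, world.proteome, 3)[:500]
        results = kinase_enrichment(motifs, pe, ue, ce, nonredundant=False)
        for r in results:
            for count, denom, freq in (
                (r.count_phos, r.denom_phos, r.freq_phos),
                (r.count_unmod, r.denom_unmod, r.freq_unmod),
                (r.count_phosphoproteome, r.denom_phosphoproteome, r.freq_phosphoproteome),
            ):
                assert 0 <= count <= denom
                assert freq == pytest.approx(count / denom)

    def test_redundant_submotif_pruned(self):
        # R[pS/pT] matches a subset of what [pS/pT] alone matches; with the
        # shorter motif retained the longer redundant one must survive only
        # if it matches sites the shorter does not
        short = parse_kinase_motif("[pS/pT]")
        longer = parse_kinase_motif("X[pS/pT]")  # same match set as bare anchor
        exts = [_ext("AsPGLMKWIHDR"), _ext("GtAGLMKWIHDR")]
        res = kinase_enrichment([short, longer], exts, exts, exts, nonredundant=True)
        assert [r.motif.text for r in res] == ["[pS/pT]"]

    def test_planted_proline_signature_detected(self, world):
        from phlaii.peptidome_io import extend_peptide_context
        from phlaii.pipeline import interactions_from_truth

        motif = parse_kinase_motif("[pS/pT]P")
        phos = [
            ModPeptide.from_mod_string(t.mod_sequence)
            for t in world.truth
            if t.kind == "ligand_phos"
        ]
        pe = [extend_peptide_context(p, world.proteome, 1) for p in phos]
        count, denom = scan_kinase_motif(motif, pe)
        # planted proline-after-phosphosite rate ~= 7.4%
        assert abs(count / denom - world.config.p_next_proline_phospho) < 0.03
        ce = extend_catalogue_sites(world.catalogue, world.proteome, 1)
        cc, cd = scan_kinase_motif(motif, ce)
        # catalogue mixes 32% extras with planted ligand sites: still far
        # above the ligand rate
        assert cc / cd > 2 * (count / denom)


class TestOddsRatio:
    def test_hand_built_table(self):
        universe = set(range(10))
        lig = {0, 1, 2, 3, 4}
        mot = {3, 4, 5, 6, 7}
        res = source_gene_overlap_odds_ratio(lig, mot, universe)
        # table [[2,3],[3,2]] -> (2*2)/(3*3)
        assert res.odds_ratio == pytest.approx(4 / 9)
        assert not res.corrected

    def test_zero_cell_triggers_haldane_correction(self):
        universe = set(range(8))
        lig = {0, 1, 2, 3}
        mot = {0, 1}  # subset: c = 0
        res = source_gene_overlap_odds_ratio(lig, mot, universe)
        assert res.corrected
        assert res.table[1, 0] == 0
        assert np.isfinite(res.odds_ratio)

    def test_independent_sets_give_odds_near_one(self, rng):
        ors = []
        universe = set(range(400))
        for _ in range(100):
            lig = set(rng.choice(400, 150, replace=False).tolist())
            mot = set(rng.choice(400, 150, replace=False).tolist())
            ors.append(source_gene_overlap_odds_ratio(lig, mot, universe).odds_ratio)
        assert 0.9 < float(np.mean(ors)) < 1.1

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            source_gene_overlap_odds_ratio(set(), set(), set())

    def test_sets_must_be_subsets(self):
        with pytest.raises(ValueError, match="subsets"):
            source_gene_overlap_odds_ratio({"x"}, set(), {"y"})
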