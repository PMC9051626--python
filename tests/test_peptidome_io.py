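"""Identification-table parsing, PSM filtering and context extension."""

import warnings

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phlaii.alphabet import SENTINEL, bracket_annotation, parse_bracket_annotation
from phlaii.peptidome_io import (
    MAXQUANT_COLUMNS,
    ModPeptide,
    PSMRecord,
    Proteome,
    SampleManifest,
    SchemaError,
    extend_peptide_context,
    filter_psms,
    read_manifest,
    read_psm_table,
    write_manifest,
    write_psm_table,
)


def _psm(seq="ASKDPSSRLMNE", phospho=(5,), score=100.0, delta=50.0, probs=None, sample="s1"):
    pep = ModPeptide(seq, frozenset(phospho), ("PROT1",))
    if probs is None:
        probs = (0.99,) * len(phospho)
    return PSMRecord(pep, score, delta, probs, sample)


class TestModPeptide:
    def test_phospho_position_must_be_sty(self):
        with pytest.raises(ValueError, match="not S/T/Y"):
            ModPeptide("AAKAAA", frozenset({0}))
        with pytest.raises(ValueError, match="outside"):
            ModPeptide("ASK", frozenset({5}))

    def test_mod_sequence_lowercases_phosphosites(self):
        pep = ModPeptide("ASKTY", frozenset({1, 3, 4}))
        assert pep.mod_sequence == "AsKty"
        assert pep.n_phospho == 3
        assert pep.phospho_residues == {1: "S", 3: "T", 4: "Y"}

    def test_identical_sequences_with_different_sites_are_distinct(self):
        a = ModPeptide("ASKSAA", frozenset({1}))
        b = ModPeptide("ASKSAA", frozenset({3}))
        assert a.key != b.key

    def test_bracket_annotation_round_trip(self):
        mod = ModPeptide("ASKDPSSR", frozenset({5})).mod_sequence
        assert bracket_annotation(mod) == "ASKDPS[p]SR"
        assert parse_bracket_annotation("ASKDPS[p]SR") == mod


class TestReadPsmTable:
    def test_phospho_position_parsed_from_modified_sequence(self, tmp_path):
        # "ASKDPSSR" with phospho on the serine at 0-based position 5
        path = tmp_path / "msms.tsv"
        write_psm_table([_psm(seq="ASKDPSSR", phospho=(5,))], path)
        result = read_psm_table(path)
        assert len(result.records) == 1
        assert result.records[0].peptide.phospho_positions == frozenset({5})

    def test_header_only_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_psm_table([], path)
        result = read_psm_table(path)
        assert result.records == [] and result.n_rows == 0

    def test_round_trip_on_synthetic_fixture(self, tmp_path, world):
        records = world.psms[:10]
        path = tmp_path / "ten.tsv"
        write_psm_table(records, path)
        back = read_psm_table(path).records
        assert len(back) == 10
        for a, b in zip(records, back):
            assert a.peptide.key == b.peptide.key
            assert a.sample_id == b.sample_id
            assert a.peptide_score == pytest.approx(b.peptide_score, rel=1e-6)
            assert a.delta_score == pytest.approx(b.delta_score, rel=1e-6)
            assert a.localization_probs == pytest.approx(b.localization_probs, rel=1e-4)

    def test_missing_column_is_fatal_and_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        df = pd.DataFrame({c: [] for c in MAXQUANT_COLUMNS.values() if c != "Score"})
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="Score"):
            read_psm_table(path)

    def test_malformed_modification_row_is_counted_not_dropped_silently(self, tmp_path):
        path = tmp_path / "mixed.tsv"
        write_psm_table([_psm(), _psm(seq="LMNPQRSTVWEK", phospho=(7,))], path)
        df = pd.read_csv(path, sep="\t")
        df.loc[0, "Modified sequence"] = "_AS(unknownmod)KDPSSRLMNE_"
        df.to_csv(path, sep="\t", index=False)
        with pytest.warns(UserWarning, match="unknownmod"):
            result = read_psm_table(path)
        assert result.n_rows == 2
        assert len(result.records) == 1
        assert result.n_excluded == 1

    def test_oxidation_and_acetylation_parsed_then_ignored(self, tmp_path):
        path = tmp_path / "ox.tsv"
        write_psm_table([_psm(seq="AMKDPSSR", phospho=(5,))], path)
        df = pd.read_csv(path, sep="\t")
        df.loc[0, "Modified sequence"] = "_(ac)AM(ox)KDPS(ph)SR_"
        df.to_csv(path, sep="\t", index=False)
        rec = read_psm_table(path).records[0]
        assert rec.peptide.sequence == "AMKDPSSR"
        assert rec.peptide.phospho_positions == frozenset({5})


class TestFilterPsms:
    def test_score_just_below_threshold_excluded(self):
        assert filter_psms([_psm(score=39.9)]) == []
        assert len(filter_psms([_psm(score=40.0)])) == 1

    def test_short_peptide_excluded_despite_high_scores(self):
        eleven = _psm(seq="ASKDPSSRLMN", phospho=(5,), score=100, delta=50)
        assert len(eleven.peptide) == 11
        assert filter_psms([eleven]) == []

    def test_localization_probability_boundary_is_strict(self):
        assert filter_psms([_psm(probs=(0.75,))]) == []
        assert len(filter_psms([_psm(probs=(0.7501,))])) == 1

    def test_delta_score_threshold(self):
        assert filter_psms([_psm(delta=9.99)]) == []

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 200, allow_nan=False),
                st.floats(0, 100, allow_nan=False),
                st.floats(0, 1, allow_nan=False),
                st.integers(8, 30),
            ),
            max_size=30,
        )
    )
    def test_idempotent_and_subsequence(self, rows):
        records = [
            _psm(seq="A" * (n - 2) + "SK", phospho=(n - 2,), score=s, delta=d, probs=(p,))
            for s, d, p, n in rows
        ]
        once = filter_psms(records)
        assert filter_psms(once) == once
        it = iter(records)
        assert all(any(r is x for x in it) for r in once)  # subsequence, order kept


class TestContextExtension:
    def test_interior_peptide_extended_both_sides(self):
        prot = Proteome({"P1": "ACCDEFGHIKL"})
        pep = ModPeptide("DEFGH", frozenset(), ("P1",))
        ext = extend_peptide_context(pep, prot, flank=2)
        assert ext.text == "CC" + "DEFGH" + "IK"
        assert ext.offset == 2 and ext.matched

    def test_protein_start_padded_with_sentinels(self):
        prot = Proteome({"P1": "DEFGHIKL"})
        ext = extend_peptide_context(ModPeptide("DEFGH", frozenset(), ("P1",)), prot, 2)
        assert ext.text.startswith(SENTINEL * 2)
        assert ext.text == SENTINEL * 2 + "DEFGH" + "IK"

    def test_no_match_flagged_and_sentinel_padded(self):
        prot = Proteome({"P1": "DEFGHIKL"})
        with pytest.warns(UserWarning, match="no exact match"):
            ext = extend_peptide_context(ModPeptide("WWWWW", frozenset()), prot, 3)
        assert ext.text == SENTINEL * 3 + "WWWWW" + SENTINEL * 3
        assert not ext.matched

    def test_lexicographically_smallest_protein_wins(self):
        prot = Proteome({"B": "AAADEFGHAAA", "A": "CCCDEFGHCCC"})
        ext = extend_peptide_context(ModPeptide("DEFGH", frozenset()), prot, 2)
        assert ext.protein_id == "A"
        assert ext.text == "CC" + "DEFGH" + "CC"

    def test_extensions_match_brute_force_slices(self, world):
        # planted peptides against an independent substring search
        checked = 0
        for t in world.truth:
            if t.kind != "ligand_phos" or checked >= 20:
                continue
            pep = ModPeptide.from_mod_string(t.mod_sequence, (t.protein_id,))
            ext = extend_peptide_context(pep, world.proteome, flank=4)
            # brute-force oracle: scan every protein with str.find
            hits = [
                (pid, s)
                for pid, seq in world.proteome.items()
                for s in range(len(seq))
                if seq.startswith(pep.sequence, s)
            ]
            pid, s = sorted(hits)[0]
            seq = world.proteome[pid]
            left = seq[max(0, s - 4) : s]
            right = seq[s + len(pep) : s + len(pep) + 4]
            expect = (
                SENTINEL * (4 - len(left)) + left + pep.mod_sequence + right
                + SENTINEL * (4 - len(right))
            )
            assert ext.text == expect
            checked += 1
        assert checked == 20


class TestManifests:
    def test_round_trip(self, tmp_path):
        ms = {
            "s1": SampleManifest("s1", ("DRB1_01_01", "DRB1_03_01"), "both"),
            "s2": SampleManifest("s2", ("DRB1_15_01",), "DR-only"),
        }
        path = tmp_path / "manifest.tsv"
        write_manifest(ms, path)
        back = read_manifest(path)
        assert back == ms

    def test_duplicate_alleles_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SampleManifest("s1", ("DRB1_01_01", "DRB1_01_01"))

    def test_empty_allele_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SampleManifest("s1", ())


def test_catalogue_validates_against_proteome(world):
    world.catalogue.validate_against(world.proteome)  # planted sites must agree
    from phlaii.peptidome_io import PhosphositeCatalogue

    bad = PhosphositeCatalogue(((next(iter(world.proteome.sequences)), 10**9, "S"),))
    with pytest.raises(ValueError, match="does not match"):
        bad.validate_against(world.proteome)
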