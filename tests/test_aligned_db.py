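"""Parsing, coordinates, residue maps, and the species difference matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taxopep.db import (
    SpeciesDatabase,
    build_difference_matrix,
    build_global_index,
    build_residue_maps,
    filter_by_gene_count,
    gapless_sequences,
    normalize_il,
    parse_database,
    write_gapless_fasta,
)

from oracles import brute_difference_matrix, random_toy_db


class TestParsing:
    def test_pseudo_uniprot_header(self, toy_db):
        assert "Bos taurus" in toy_db.species()
        assert toy_db.taxon_ids["Bos taurus"] == 9913
        assert set(toy_db.gene_order) == {"COL1A1", "COL1A2"}
        assert toy_db.gene_alignments["COL1A1"]["Bos taurus"] == "GPAGPKGELGPVG-"

    def test_uniprot_header(self, toy_db):
        # the sp|...| record must land on the same species as the NCBI ones
        assert toy_db.gene_alignments["COL1A2"]["Bos taurus"] == "MLSFVDTR--"

    def test_empty_input(self):
        db = parse_database("")
        assert db.species() == []

    def test_missing_tags_rejected(self, caplog):
        fasta = ">sp|X|X_HUMAN no tags here\nACDE\n"
        db = parse_database(fasta)
        assert db.species() == []

    def test_unknown_gene_rejected(self):
        fasta = ">a | b | c OS = Bos taurus GN = NOTAGENE\nACDE\n"
        assert parse_database(fasta).species() == []

    def test_isoform_collapse_majority_and_tie(self):
        # two isoforms "AC-" / "AG-": col 2 ties C/G -> alphabetical C
        fasta = (
            ">x | a | a OS = Sp one GN = COL1A1\nAC-\n"
            ">x | b | b OS = Sp one GN = COL1A1\nAG-\n"
        )
        db = parse_database(fasta)
        assert db.gene_alignments["COL1A1"]["Sp one"] == "AC-"

    def test_isoform_collapse_gap_majority(self):
        fasta = (
            ">x | a | a OS = S GN = COL1A1\nA--\n"
            ">x | b | b OS = S GN = COL1A1\nA-C\n"
            ">x | c | c OS = S GN = COL1A1\nAGC\n"
        )
        db = parse_database(fasta)
        # col2: 2/3 gaps -> gap; col3: 2/3 C -> C
        assert db.gene_alignments["COL1A1"]["S"] == "A-C"

    def test_unequal_lengths_hard_error_names_gene(self):
        fasta = (
            ">x | a | a OS = A GN = COL1A1\nACDE\n"
            ">x | b | b OS = B GN = COL1A1\nACD\n"
        )
        with pytest.raises(ValueError, match="COL1A1"):
            parse_database(fasta)

    def test_ambiguous_residues_become_gaps(self):
        fasta = ">x | a | a OS = A GN = COL1A1\nACXBZ\n"
        db = parse_database(fasta)
        assert db.gene_alignments["COL1A1"]["A"] == "AC---"


class TestNormalizeIL:
    def test_substitution(self):
        assert normalize_il("ISOLATE") == "LSOLATE"
        assert normalize_il("PEPTDE") == "PEPTDE"

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY-", max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_idempotent_and_complete(self, seq):
        once = normalize_il(seq)
        assert "I" not in once
        assert normalize_il(once) == once

    def test_database_normalization(self, toy_db):
        ndb = normalize_il(toy_db)
        for gene in ndb.gene_order:
            for seq in ndb.gene_alignments[gene].values():
                assert "I" not in seq


class TestGeneCountFilter:
    def _db_with_counts(self, counts):
        genes = [f"G{i:02d}" for i in range(20)]
        alignments = {g: {} for g in genes}
        for sp, n in counts.items():
            for g in genes[:n]:
                alignments[g][sp] = "ACDE"
        alignments = {g: s for g, s in alignments.items() if s}
        return SpeciesDatabase(gene_alignments=alignments, gene_set=tuple(genes))

    def test_boundary_of_missing_rule(self):
        db = self._db_with_counts({"full": 20, "fifteen": 15, "fourteen": 14})
        out, report = filter_by_gene_count(db, max_missing=5)
        assert set(out.species()) == {"full", "fifteen"}
        removed = report[report["removed"]]["species"].tolist()
        assert removed == ["fourteen"]

    def test_idempotent(self):
        db = self._db_with_counts({"a": 20, "b": 10})
        once, _ = filter_by_gene_count(db)
        twice, report = filter_by_gene_count(once)
        assert twice.species() == once.species()
        assert not report["removed"].any()

    def test_decoys_exempt(self):
        db = self._db_with_counts({"a": 20, "DECOY_001": 3})
        out, _ = filter_by_gene_count(db)
        assert "DECOY_001" in out.species()


class TestGlobalIndex:
    def test_alphabetical_concatenation(self):
        db = SpeciesDatabase(
            gene_alignments={"B": {"S": "AC"}, "A": {"S": "DEF"}},
            gene_set=("A", "B"),
        )
        idx = build_global_index(db)
        assert idx.total_length == 5
        assert [idx.site("A", c) for c in (1, 2, 3)] == [1, 2, 3]
        assert [idx.site("B", c) for c in (1, 2)] == [4, 5]

    def test_round_trip_all_columns(self, rng):
        db = random_toy_db(rng)
        idx = build_global_index(db)
        assert idx.total_length == sum(
            db.alignment_length(g) for g in db.gene_order
        )
        for gene in db.gene_order:
            for col in range(1, db.alignment_length(gene) + 1):
                assert idx.locate(idx.site(gene, col)) == (gene, col)

    def test_out_of_range(self):
        db = SpeciesDatabase(gene_alignments={"A": {"S": "AC"}}, gene_set=("A",))
        idx = build_global_index(db)
        with pytest.raises(IndexError):
            idx.locate(3)


class TestResidueMaps:
    def test_gap_skipped(self):
        db = SpeciesDatabase(gene_alignments={"A": {"S": "A-C"}}, gene_set=("A",))
        idx = build_global_index(db)
        maps = build_residue_maps(db, idx)
        assert maps[("S", "A")].tolist() == [1, 3]

    def test_all_gap_empty(self):
        db = SpeciesDatabase(
            gene_alignments={"A": {"S": "---", "T": "ACD"}}, gene_set=("A",)
        )
        maps = build_residue_maps(db, build_global_index(db))
        assert maps[("S", "A")].tolist() == []

    def test_gapless_reconstruction_round_trip(self, rng):
        db = random_toy_db(rng)
        idx = build_global_index(db)
        maps = build_residue_maps(db, idx)
        for (sp, gene), gapless in gapless_sequences(db).items():
            full = db.concat(sp)
            rebuilt = "".join(full[s - 1] for s in maps[(sp, gene)])
            assert rebuilt == gapless


class TestDifferenceMatrix:
    def test_identical_species_empty(self):
        db = SpeciesDatabase(
            gene_alignments={"A": {"S": "ACD", "T": "ACD"}}, gene_set=("A",)
        )
        diff = build_difference_matrix(db, build_global_index(db))
        assert diff.diff("S", "T") == []

    def test_gap_sites_ignored(self):
        db = SpeciesDatabase(
            gene_alignments={"A": {"S": "AC-", "T": "AG-"}}, gene_set=("A",)
        )
        diff = build_difference_matrix(db, build_global_index(db))
        assert diff.diff("S", "T") == [(2, "C", "G")]

    def test_symmetry_under_swap(self, toy_db):
        diff = build_difference_matrix(toy_db, build_global_index(toy_db))
        for a, b in diff.pairs():
            fwd = diff.diff(a, b)
            rev = diff.diff(b, a)
            assert [(s, y, x) for s, x, y in fwd] == rev
            assert all(x != y and "-" not in (x, y) for _, x, y in fwd)

    def test_matches_brute_force_on_random_toys(self, rng):
        for _ in range(5):
            db = random_toy_db(rng)
            diff = build_difference_matrix(db, build_global_index(db))
            expected = brute_difference_matrix(db)
            for pair, entries in expected.items():
                assert diff.diff(*pair) == entries


def test_gapless_export_round_trip(tmp_path, toy_db):
    path = tmp_path / "gapless.fasta"
    write_gapless_fasta(toy_db, path)
    reparsed = parse_database(str(path))
    assert set(reparsed.species()) == set(toy_db.species())
    got = gapless_sequences(reparsed)
    for key, seq in gapless_sequences(toy_db).items():
        assert got[key] == seq
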