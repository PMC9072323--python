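"""The synthetic database / evidence generator."""

import io

import numpy as np
import pandas as pd
import pytest

from taxopep.db import (
    SpeciesDatabase,
    build_difference_matrix,
    build_global_index,
    normalize_il,
    parse_database,
    write_aligned_fasta,
)
from taxopep.evidence import filter_precursor_fdr, flag_contaminants, load_contaminants, read_evidence
from taxopep.pipeline import PipelineParams, run_study
from taxopep.qc import relative_protease_intensity
from taxopep.simulate import (
    SimulationConfig,
    add_sister_species,
    digest_in_silico,
    make_protease_fasta,
    simulate_cohort,
    simulate_database,
    simulate_evidence,
    write_maxquant_evidence,
    write_spectronaut_report,
)


class TestSimulateDatabase:
    def test_zero_divergence_all_identical(self):
        cfg = SimulationConfig(seed=3, n_species=4, divergence=0.0,
                               missing_gene_rate=0.0)
        db = simulate_database(cfg)
        diff = build_difference_matrix(db, build_global_index(db))
        assert all(diff.n_diff(a, b) == 0 for a, b in diff.pairs())

    def test_pairwise_differences_near_expectation(self):
        # two leaves, each branch substitutes sites with prob in
        # [0.5, 1.5] * divergence; observed differences must fall inside a
        # generous binomial envelope around the compound expectation
        cfg = SimulationConfig(
            seed=11, n_species=2, divergence=0.2, missing_gene_rate=0.0,
            gene_lengths=(2000,), gene_names=("COL1A1",),
        )
        db = simulate_database(cfg)
        diff = build_difference_matrix(db, build_global_index(db))
        n = diff.n_diff(*list(diff.pairs())[0])
        L = 2000
        # two independent branches at p in [0.1, 0.3]; differing when exactly
        # one substitutes away, or both substitute to different residues
        lo = L * (2 * 0.1 * 0.9 * (19 / 20)) * 0.5
        hi = L * (2 * 0.3 + 0.3 ** 2) * 1.5
        assert lo < n < hi

    def test_fixed_seed_identical_fasta(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_species=6)
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        write_aligned_fasta(simulate_database(cfg), p1)
        write_aligned_fasta(simulate_database(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_too_few_species_errors(self):
        with pytest.raises(ValueError):
            simulate_database(SimulationConfig(n_species=1))

    def test_output_parses_through_database_module(self, tmp_path):
        cfg = SimulationConfig(seed=5, n_species=4)
        db = simulate_database(cfg)
        path = tmp_path / "db.fa"
        write_aligned_fasta(db, path)
        reparsed = parse_database(str(path), gene_set=cfg.gene_names)
        assert reparsed.species() == db.species()
        for g in db.gene_order:
            assert reparsed.gene_alignments[g] == db.gene_alignments[g]

    def test_heldout_species_absent_from_database(self):
        db, novel = simulate_database(SimulationConfig(seed=2, n_species=4),
                                      heldout=True)
        assert novel.species() == ["Novelis_heldout"]
        assert "Novelis_heldout" not in db.species()

    def test_sister_species_exact_difference_count(self, rng):
        db = simulate_database(SimulationConfig(seed=9, n_species=4,
                                                missing_gene_rate=0.0))
        sister = add_sister_species(db, "Species_001", 12, rng)
        diff = build_difference_matrix(db, build_global_index(db))
        assert diff.n_diff("Species_001", sister) == 12


class TestDigest:
    @pytest.fixture
    def mini_db(self):
        return SpeciesDatabase(
            gene_alignments={"G": {"S": "AAAAKRPCCCCCKDDDDDDR"}}, gene_set=("G",)
        )

    def test_no_cleavage_before_proline(self, mini_db):
        peps = digest_in_silico("S", mini_db, length_range=(1, 50))
        # cleavage after K5 and K13 and R20 only; R6 is followed by P
        assert "AAAAK" in peps
        assert "RPCCCCCK" in peps
        assert not any(p.startswith("PCCCCC") for p in peps)

    def test_fully_tryptic_when_p_semitryptic_zero(self, mini_db):
        seq = "AAAAKRPCCCCCKDDDDDDR"
        for pep in digest_in_silico("S", mini_db, p_semitryptic=0.0,
                                    length_range=(1, 50)):
            start = seq.find(pep)
            assert start != -1
            assert start == 0 or (seq[start - 1] in "KR" and seq[start] != "P")
            end = start + len(pep)
            assert end == len(seq) or (pep[-1] in "KR" and seq[end] != "P")

    def test_all_peptides_are_substrings(self, rng):
        db = simulate_database(SimulationConfig(seed=4, n_species=3))
        sp = db.species()[0]
        full = db.concat(sp).replace("-", "")
        peps = digest_in_silico(sp, db, p_semitryptic=0.5, rng=rng)
        assert peps
        assert all(p in full for p in peps)
        assert all(7 <= len(p) <= 30 for p in peps)


class TestSimulateEvidence:
    def test_blank_is_protease_dominated(self):
        cfg = SimulationConfig(seed=8, n_species=4)
        db = simulate_database(cfg)
        rng = np.random.default_rng(8)
        contam = make_protease_fasta(db, rng)
        ev = simulate_evidence(db, cfg, rng=rng, raw_file="blank",
                               contaminant_fasta=contam, is_blank=True)
        ev = filter_precursor_fdr(ev)
        ev = flag_contaminants(ev, load_contaminants(contam))
        assert relative_protease_intensity(ev) == 1.0

    def test_realized_protease_share_close_to_configured(self):
        cfg = SimulationConfig(seed=12, n_species=4,
                               protease_relative_intensity=0.2)
        cfg.true_species = "Species_002"
        db = simulate_database(cfg)
        rng = np.random.default_rng(12)
        contam = make_protease_fasta(db, rng)
        ev = simulate_evidence(db, cfg, rng=rng, raw_file="s",
                               contaminant_fasta=contam)
        ev = filter_precursor_fdr(ev)
        ev = flag_contaminants(ev, load_contaminants(contam))
        assert relative_protease_intensity(ev) == pytest.approx(0.2, abs=0.05)

    def test_coverage_target_zero_is_blank_like(self):
        cfg = SimulationConfig(seed=13, n_species=4, target_site_coverage=0)
        db = simulate_database(cfg)
        rng = np.random.default_rng(13)
        contam = make_protease_fasta(db, rng)
        ev = simulate_evidence(db, cfg, rng=rng, raw_file="s",
                               contaminant_fasta=contam)
        ev = filter_precursor_fdr(ev)
        ev = flag_contaminants(ev, load_contaminants(contam))
        assert relative_protease_intensity(ev) > 0.9

    def test_determinism_byte_identical_tables(self, tmp_path):
        cfg = SimulationConfig(seed=21, n_species=5)
        paths = []
        for name in ("a", "b"):
            study = simulate_cohort(cfg, n_samples=3, n_novel=1, n_blanks=1)
            p = tmp_path / f"{name}.tsv"
            write_spectronaut_report(study.evidence, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_round_trip_through_readers(self, tmp_path):
        cfg = SimulationConfig(seed=22, n_species=4)
        study = simulate_cohort(cfg, n_samples=2, n_novel=0, n_blanks=1)
        sp_path = tmp_path / "report.tsv"
        mq_path = tmp_path / "evidence.txt"
        write_spectronaut_report(study.evidence, sp_path)
        write_maxquant_evidence(study.evidence, mq_path)
        sp = read_evidence(sp_path, "spectronaut_report")
        expected = study.evidence.sort_values(
            ["raw_file", "modified_seq", "charge"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            sp[["raw_file", "stripped_seq", "charge"]],
            expected[["raw_file", "stripped_seq", "charge"]],
        )
        np.testing.assert_allclose(sp["intensity"], expected["intensity"])
        # the MaxQuant dialect is pre-filtered and q-less
        mq = read_evidence(mq_path, "maxquant_evidence")
        assert mq["precursor_q"].isna().all()
        assert len(mq) == (expected["precursor_q"] <= 0.01).sum()

    def test_true_species_recovered_single_run(self):
        cfg = SimulationConfig(seed=31, n_species=10)
        cfg.true_species = "Species_007"
        study = simulate_cohort(cfg, n_samples=1, n_novel=0, n_blanks=1)
        res = run_study(study.db, study.evidence, study.contaminant_fasta,
                        study.sample_annotations, None, PipelineParams(seed=1))
        row = res.results[res.results["raw_file"] == "sample_001"].iloc[0]
        assert "Species_007" in row["species"].split(";")
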