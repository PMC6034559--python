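"""Synthetic-data generators: planted truth, calibration, determinism."""

import io
import math

import numpy as np
import pytest

from raretaxa.genomes import reverse_complement
from raretaxa.io import write_genomeset, write_proteome
from raretaxa.peptides import digest
from raretaxa.simulate import (
    SimulationConfig, generate_abundance_tables, generate_pangenome,
    generate_proteomes, generate_qpcr_run, generate_siga_cohort,
)


def _fasta_bytes(writer, obj):
    import tempfile, pathlib
    with tempfile.TemporaryDirectory() as d:
        path = pathlib.Path(d) / "x.fasta"
        writer(obj, path)
        return path.read_bytes()


class TestConfigValidation:
    def test_rejects_overfull_conserved(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_reference_genes=5, n_conserved=6)

    def test_rejects_shared_exceeding_conserved(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_conserved=3, n_exclusion_shared=4)

    def test_rejects_hypermutation_and_bad_medians(self):
        with pytest.raises(ValueError):
            SimulationConfig(point_mutation_rate=0.3)
        with pytest.raises(ValueError):
            SimulationConfig(siga_median_pos=-1.0)


class TestPangenome:
    def test_planted_marker_count_by_construction(self, small_pangenome):
        _, _, truth = small_pangenome
        assert len(truth.marker_gene_ids) == 3  # 4 conserved - 1 shared
        assert truth.marker_gene_ids == \
            truth.conserved_gene_ids - truth.exclusion_shared_gene_ids

    def test_mutation_free_copies_are_identical(self, small_pangenome):
        inclusion, _, truth = small_pangenome
        ref_seqs = {r.gene_id: r.sequence for r in inclusion.genomes["ref"]}
        for genome_id in inclusion.genome_ids:
            if genome_id == "ref":
                continue
            sequences = {g.sequence for g in inclusion.genomes[genome_id]}
            for gid in truth.conserved_gene_ids:
                assert ref_seqs[gid] in sequences or \
                    reverse_complement(ref_seqs[gid]) in sequences

    def test_ground_truth_matches_substring_scan(self, small_pangenome):
        """Brute-force scan of the emitted sequences recovers the planted sets."""
        inclusion, exclusion, truth = small_pangenome
        ref_seqs = {r.gene_id: r.sequence for r in inclusion.genomes["ref"]}
        others = [g for g in inclusion.genome_ids if g != "ref"]

        def occurs(seq, genome_set, genome_id):
            pool = {g.sequence for g in genome_set.genomes[genome_id]}
            return seq in pool or reverse_complement(seq) in pool

        scanned_conserved = {
            gid for gid, seq in ref_seqs.items()
            if all(occurs(seq, inclusion, g) for g in others)
        }
        scanned_shared = {
            gid for gid, seq in ref_seqs.items()
            if any(occurs(seq, exclusion, g) for g in exclusion.genome_ids)
        }
        assert scanned_conserved == truth.conserved_gene_ids
        assert scanned_shared == truth.exclusion_shared_gene_ids

    def test_byte_identical_under_same_seed(self, small_config):
        a = _fasta_bytes(write_genomeset, generate_pangenome(small_config)[0])
        b = _fasta_bytes(write_genomeset, generate_pangenome(small_config)[0])
        assert a == b

    def test_no_exclusion_genomes_means_no_shared_genes(self):
        config = SimulationConfig(n_exclusion_genomes=0)
        _, exclusion, truth = generate_pangenome(config)
        assert exclusion.n_genomes == 0
        assert truth.exclusion_shared_gene_ids == set()
        assert truth.marker_gene_ids == truth.conserved_gene_ids


class TestSigaCohort:
    def test_group_sizes_and_columns(self):
        cohort = generate_siga_cohort(SimulationConfig(seed=7))
        assert (cohort["sfb_status"] == "positive").sum() == 23
        assert (cohort["sfb_status"] == "negative").sum() == 24
        assert cohort["age_months"].between(8, 48).all()

    def test_sample_median_near_parameter(self):
        cohort = generate_siga_cohort(SimulationConfig(seed=7, siga_log_sd=0.4))
        med = cohort.loc[cohort.sfb_status == "positive", "siga_ug_ml"].median()
        assert abs(med - 118.60) / 118.60 < 0.25

    def test_monte_carlo_calibration(self):
        """Mean of positive-group sample medians over 200 replicates within 5%."""
        medians = []
        for seed in range(200):
            cohort = generate_siga_cohort(SimulationConfig(seed=seed))
            medians.append(cohort.loc[cohort.sfb_status == "positive",
                                      "siga_ug_ml"].median())
        assert abs(np.mean(medians) - 118.60) / 118.60 < 0.05

    def test_degenerate_spread_collapses_to_median(self):
        cohort = generate_siga_cohort(SimulationConfig(siga_log_sd=0.0))
        pos = cohort.loc[cohort.sfb_status == "positive", "siga_ug_ml"]
        assert np.allclose(pos, 118.60)

    def test_empty_positive_group_allowed(self):
        cohort = generate_siga_cohort(SimulationConfig(n_pos_subjects=0))
        assert (cohort["sfb_status"] == "positive").sum() == 0


class TestQpcrGeneration:
    def test_noise_free_model_ct(self):
        config = SimulationConfig(seed=1, curve_slope=-3.3219, curve_intercept=37.0,
                                  ct_noise_sd=0.0)
        run = generate_qpcr_run(config, {"S1": 1e4}, sample_replicates=1)
        ct = run.samples.query("target == 'SFB'")["ct"].iloc[0]
        assert ct == pytest.approx(37.0 - 3.3219 * 4, abs=1e-9)

    def test_single_copy_ct_is_intercept(self):
        config = SimulationConfig(ct_noise_sd=0.0)
        run = generate_qpcr_run(config, {"S1": 1.0}, sample_replicates=1)
        ct = run.samples.query("target == 'SFB'")["ct"].iloc[0]
        assert ct == pytest.approx(config.curve_intercept)

    def test_deterministic_under_seed(self):
        config = SimulationConfig(seed=9, ct_noise_sd=0.2)
        loads = {"S1": 1e5, "S2": 3e3}
        a = generate_qpcr_run(config, loads)
        b = generate_qpcr_run(config, loads)
        assert a.curve_points.equals(b.curve_points)
        assert a.samples.equals(b.samples)

    def test_rejects_nonpositive_loads(self):
        with pytest.raises(ValueError):
            generate_qpcr_run(SimulationConfig(), {"S1": 0.0})


class TestProteomes:
    def test_digestion_releases_each_planted_peptide(self, default_proteomes):
        inclusion, _, truth = default_proteomes
        for pep in truth.planted_unique_peptides:
            hosts = [seq for seq in inclusion.values() if pep in seq]
            assert hosts
            assert any(pep in {p.sequence for p in digest(host)} for host in hosts)

    def test_specific_published_peptide_released(self, default_proteomes):
        inclusion, _, _ = default_proteomes
        host = next(seq for seq in inclusion.values() if "EMMDQPEFK" in seq)
        assert "EMMDQPEFK" in {p.sequence for p in digest(host)}

    def test_no_planted_list_shares_nothing(self):
        """With nothing planted, the proteomes share no peptide of length >= 4."""
        inclusion, background, _ = generate_proteomes(
            SimulationConfig(seed=3), planted_peptides=[], n_shared_decoys=0)
        background_blob = "|".join(background.values())
        for seq in inclusion.values():
            for pep in digest(seq, max_missed=2, min_length=4):
                assert pep.sequence not in background_blob

    def test_byte_identical_under_same_seed(self):
        config = SimulationConfig(seed=4)
        a = _fasta_bytes(write_proteome, generate_proteomes(config)[0])
        b = _fasta_bytes(write_proteome, generate_proteomes(config)[0])
        assert a == b

    def test_rejects_invalid_residues(self):
        with pytest.raises(ValueError):
            generate_proteomes(SimulationConfig(), planted_peptides=["PEPTIBE1"])


class TestAbundance:
    def test_directional_shifts_and_diversity(self):
        from raretaxa.cohort import shannon_index
        from raretaxa.simulate import ABUNDANCE_TAXA_DOWN, ABUNDANCE_TAXA_UP
        table, groups = generate_abundance_tables(
            SimulationConfig(seed=0), n_pos_samples=8, n_neg_samples=8)
        pos = table[groups == "positive"]
        neg = table[groups == "negative"]
        for taxon in ABUNDANCE_TAXA_UP:
            assert pos[taxon].mean() > neg[taxon].mean()
        for taxon in ABUNDANCE_TAXA_DOWN:
            assert neg[taxon].mean() > pos[taxon].mean()
        assert np.allclose(table.sum(axis=1), 1.0)
        h_pos = pos.apply(shannon_index, axis=1).mean()
        h_neg = neg.apply(shannon_index, axis=1).mean()
        assert h_pos > h_neg
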