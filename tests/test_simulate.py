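"""Generator contracts: determinism, truth sufficiency, filter exercise."""

import numpy as np
import pytest

from tregprov.clonality import expansion_ratio, gini_coefficient, repertoire_overlap
from tregprov.provenance import estimate_recruitment, migration_ratio, normalize_recruitment
from tregprov.repertoire import call_clonotypes, filter_paired_productive, read_contig_table
from tregprov.signature import signature_concordance
from tregprov.simulate import (
    DirichletAbundance,
    ExplicitSizes,
    ParabiosisModel,
    PowerLawAbundance,
    RepertoireModel,
    SignatureModel,
    simulate_de_table,
    simulate_parabiosis,
    simulate_photoconversion,
    simulate_repertoire,
)


class TestRepertoireGenerator:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        from pathlib import Path
        m = RepertoireModel(n_cells=50, seed=21, unpaired_fraction=0.1)
        t1 = simulate_repertoire(m, tmp_path / "a")
        t2 = simulate_repertoire(m, tmp_path / "b")
        for key in ("tenx", "airr"):
            assert Path(t1.files[key]).read_bytes() == Path(t2.files[key]).read_bytes()
        t3 = simulate_repertoire(RepertoireModel(n_cells=50, seed=22, unpaired_fraction=0.1),
                                 tmp_path / "c")
        assert Path(t1.files["tenx"]).read_bytes() != Path(t3.files["tenx"]).read_bytes()

    def test_explicit_sizes_flow_through_pipeline(self, tmp_path):
        truth = simulate_repertoire(RepertoireModel(
            n_cells=8, abundance=ExplicitSizes((3, 2, 1, 1, 1)), seed=2), tmp_path)
        records, _ = read_contig_table(truth.files["tenx"], "tenx")
        cells, _ = filter_paired_productive(records)
        rep = call_clonotypes(cells)
        assert sorted(rep.sizes) == [1, 1, 1, 2, 3]
        assert expansion_ratio(rep) == pytest.approx(0.625)
        assert gini_coefficient(rep.sizes) == pytest.approx(gini_coefficient([3, 2, 1, 1, 1]))

    def test_explicit_sizes_must_sum_to_n_cells(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_repertoire(RepertoireModel(
                n_cells=10, abundance=ExplicitSizes((3, 2)), seed=0))

    @pytest.mark.parametrize("abundance", [
        DirichletAbundance(n_clonotypes=40, concentration=0.5),
        PowerLawAbundance(n_clonotypes=40, exponent=1.5),
    ])
    def test_recovered_size_multiset_equals_truth(self, abundance):
        truth = simulate_repertoire(RepertoireModel(n_cells=120, abundance=abundance, seed=13))
        cells, _ = filter_paired_productive(truth.records)
        rep = call_clonotypes(cells)
        assert sorted(rep.sizes) == sorted(truth.clone_sizes["sample1"])

    def test_unpaired_cells_counted_exactly(self):
        truth = simulate_repertoire(RepertoireModel(
            n_cells=100, unpaired_fraction=0.1, seed=4))
        cells, report = filter_paired_productive(truth.records)
        assert truth.n_unpaired["sample1"] == 10
        assert report.n_dropped_unpaired == 10
        assert report.n_retained == 90
        rep = call_clonotypes(cells)
        assert sorted(rep.sizes) == sorted(truth.clone_sizes["sample1"])

    def test_multichain_cells_resolved_to_truth_sizes(self):
        truth = simulate_repertoire(RepertoireModel(
            n_cells=80, multichain_fraction=0.15, seed=6))
        cells, report = filter_paired_productive(truth.records)
        assert report.n_multi_chain_resolved == truth.n_multichain["sample1"] == 12
        rep = call_clonotypes(cells)
        assert sorted(rep.sizes) == sorted(truth.clone_sizes["sample1"])

    def test_planted_shared_clonotypes_recovered(self):
        truth = simulate_repertoire(RepertoireModel(
            n_cells=60, abundance=DirichletAbundance(30, 1.0),
            n_shared_planted=7, seed=8))
        cells, _ = filter_paired_productive(truth.records)
        by_sample = {}
        for c in cells:
            by_sample.setdefault(c.sample_id, []).append(c)
        reps = {s: call_clonotypes(v) for s, v in by_sample.items()}
        result = repertoire_overlap(reps["sample1"], reps["sample2"])
        assert result.shared == 7
        assert len(truth.shared_keys) == 7

    def test_dirty_repertoire_still_dissects_cleanly(self):
        """Unpaired + multichain decoys together leave truth recoverable."""
        truth = simulate_repertoire(RepertoireModel(
            n_cells=100, unpaired_fraction=0.08, multichain_fraction=0.1, seed=17))
        cells, report = filter_paired_productive(truth.records)
        assert report.n_dropped_unpaired == truth.n_unpaired["sample1"]
        assert report.n_multi_chain_resolved == truth.n_multichain["sample1"]
        rep = call_clonotypes(cells)
        assert sorted(rep.sizes) == sorted(truth.clone_sizes["sample1"])


class TestParabiosisGenerator:
    def test_noise_free_identity(self):
        truth = simulate_parabiosis(ParabiosisModel(
            n_mice=10, true_recruitment_fraction=0.6, tissue_noise_sd=0.0, seed=1))
        for m in truth.cohort:
            assert normalize_recruitment(m.blood_chimerism_pct, m.tissue_chimerism_pct) \
                == pytest.approx(60.0)

    def test_full_recruitment_noise_free(self):
        truth = simulate_parabiosis(ParabiosisModel(
            n_mice=5, true_recruitment_fraction=1.0, tissue_noise_sd=0.0, seed=2))
        for m in truth.cohort:
            assert m.tissue_chimerism_pct == pytest.approx(m.blood_chimerism_pct)

    def test_blood_chimerism_in_domain(self):
        truth = simulate_parabiosis(ParabiosisModel(
            n_mice=200, blood_chimerism_mean=5.0, blood_chimerism_sd=20.0, seed=3))
        for m in truth.cohort:
            assert 0 < m.blood_chimerism_pct <= 100
            assert m.tissue_chimerism_pct >= 0

    def test_typical_cohort_recovers_within_two_points(self):
        """Most individual 50-mouse cohorts land within 2 points of truth.

        Under the default noise model a single cohort estimate has SE near
        2 points, so individual cohorts land inside the band about two
        thirds of the time; a clear majority doing so (together with the
        aggregate unbiasedness checks elsewhere) pins the recovery claim.
        """
        seeds = [int(c.generate_state(1)[0] % 2**31)
                 for c in np.random.SeedSequence(2).spawn(60)]
        within = 0
        for seed in seeds:
            truth = simulate_parabiosis(ParabiosisModel(
                n_mice=50, true_recruitment_fraction=0.60, tissue_noise_sd=5.0,
                seed=seed))
            est = estimate_recruitment(truth.cohort, 20, 5375)
            within += abs(est.mean_recruitment_pct - 60.0) <= 2.0
        assert within / len(seeds) > 0.5

    def test_cohort_csv_round_trip(self, tmp_path):
        from tregprov.provenance import read_cohort_csv
        truth = simulate_parabiosis(ParabiosisModel(n_mice=4, seed=5), tmp_path)
        assert read_cohort_csv(truth.files["cohort"]) == truth.cohort


class TestPhotoconversionGenerator:
    def test_noise_free_ratios_recover_enrichments_exactly(self):
        truth = simulate_photoconversion(0.01, [0.5, 1.0, 3.0], noise_sd=0.0, seed=0)
        table = migration_ratio(truth.samples)
        test_rows = table[~table["is_reference"]]
        assert test_rows["migration_ratio"].tolist() == pytest.approx([0.5, 1.0, 3.0])

    def test_single_unit_enrichment(self):
        truth = simulate_photoconversion(0.02, [1.0], noise_sd=0.0)
        table = migration_ratio(truth.samples)
        assert table["migration_ratio"].tolist() == pytest.approx([1.0, 1.0])

    def test_noisy_ratios_within_three_sd(self):
        ref, noise = 0.02, 0.002
        truth = simulate_photoconversion(ref, [0.5, 3.0], noise_sd=noise, seed=11)
        table = migration_ratio(truth.samples)
        for ratio, enr in zip(table.loc[~table["is_reference"], "migration_ratio"],
                              truth.enrichments):
            assert abs(ratio - enr) <= 3 * noise / ref

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_photoconversion(0.0, [1.0])
        with pytest.raises(ValueError):
            simulate_photoconversion(0.01, [-1.0])


class TestDeTableGenerator:
    def test_fully_concordant_noise_free(self):
        truth = simulate_de_table(SignatureModel(
            n_genes=300, n_signature=60, planted_concordant_fraction=1.0,
            noise_sd_log2=0.0, seed=1))
        assert signature_concordance(truth.de_table, truth.signature).fraction_pct == 100.0

    def test_planted_fraction_exact_noise_free(self):
        truth = simulate_de_table(SignatureModel(
            n_genes=500, n_signature=100, planted_concordant_fraction=0.74,
            noise_sd_log2=0.0, seed=2))
        assert truth.n_concordant_true == 74
        result = signature_concordance(truth.de_table, truth.signature, min_fold=1.0)
        assert result.fraction_pct == pytest.approx(74.0)

    def test_noisy_concordance_near_planted_across_seeds(self):
        """Mean measured concordance over seeds stays near the planted 74%."""
        vals = []
        for seed in range(20):
            truth = simulate_de_table(SignatureModel(
                n_genes=400, n_signature=100, planted_concordant_fraction=0.74,
                effect_size_log2=2.0, noise_sd_log2=0.5, seed=seed))
            vals.append(signature_concordance(
                truth.de_table, truth.signature, min_fold=1.0).fraction_pct)
        # with effect 2.0 and sd 0.5 a sign flip is a 4-sigma event
        assert np.mean(vals) == pytest.approx(74.0, abs=1.0)

    def test_signature_larger_than_genome_rejected(self):
        with pytest.raises(ValueError):
            simulate_de_table(SignatureModel(n_genes=10, n_signature=20))

    def test_files_round_trip(self, tmp_path):
        from tregprov.signature import read_de_table, read_signature
        truth = simulate_de_table(SignatureModel(
            n_genes=200, n_signature=40, noise_sd_log2=0.0, seed=3), tmp_path)
        table = read_de_table(truth.files["de"])
        sig = read_signature(truth.files["signature"])
        direct = signature_concordance(truth.de_table, truth.signature)
        via_files = signature_concordance(table, sig)
        assert via_files.to_dict() == direct.to_dict()
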