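"""Synthetic-data generators: determinism, planted signal, conservation."""

import numpy as np
import pandas as pd
import pytest

from redrug.simulate import (
    SimulationConfig,
    demo_config,
    gene_name,
    simulate_abstracts,
    simulate_all,
    simulate_cnv_cohort,
    simulate_drug_table,
    simulate_labels,
    simulate_maf,
    simulate_ppi,
    write_inputs,
)


class TestConfig:
    def test_planted_index_bounds_checked(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, amp_spec=[(10, 6, 0.3)])

    def test_background_distribution_must_normalize(self):
        with pytest.raises(ValueError):
            SimulationConfig(background_cnv_distribution={2: 0.5})

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(hpv_positive_fraction=1.2)


class TestCnvCohort:
    def test_planted_carrier_count_exact(self):
        # background excludes level 6 so every 6 observed is a planted carrier
        background = {0: 0.004, 1: 0.004, 2: 0.976, 3: 0.004, 4: 0.004,
                      5: 0.004, 7: 0.004}
        cfg = SimulationConfig(seed=3, n_genes=50, n_samples=100,
                               amp_spec=[(7, 6, 0.30)],
                               background_cnv_distribution=background)
        df, truth = simulate_cnv_cohort(cfg)
        g7 = df[df.gene == gene_name(7)]
        assert (g7.copy_number == 6).sum() == 30
        assert truth["amplified"] == [gene_name(7)]

    def test_empty_specs_pure_null(self):
        cfg = SimulationConfig(seed=3, n_genes=20, n_samples=30)
        df, truth = simulate_cnv_cohort(cfg)
        assert truth == {"amplified": [], "deleted": []}
        # background is overwhelmingly diploid
        assert (df.copy_number == 2).mean() > 0.9

    def test_determinism(self):
        cfg = SimulationConfig(seed=11, n_genes=30, n_samples=40,
                               amp_spec=[(0, 6, 0.2)])
        df1, _ = simulate_cnv_cohort(cfg)
        df2, _ = simulate_cnv_cohort(cfg)
        pd.testing.assert_frame_equal(df1, df2)

    def test_zero_carriers_rejected(self):
        cfg = SimulationConfig(seed=0, n_genes=10, n_samples=10,
                               amp_spec=[(0, 6, 0.01)])
        with pytest.raises(ValueError):
            simulate_cnv_cohort(cfg)


class TestLabels:
    def test_positive_count_deterministic(self):
        cfg = SimulationConfig(seed=2, n_samples=100, hpv_positive_fraction=0.3)
        labels = simulate_labels(cfg)
        assert (labels.hpv_status == "positive").sum() == 30
        pd.testing.assert_frame_equal(labels, simulate_labels(cfg))


class TestMaf:
    def test_row_count_conserved(self):
        cfg = SimulationConfig(seed=5, n_genes=100, n_samples=50,
                               n_total_mutations=800)
        maf, _, _ = simulate_maf(cfg)
        assert len(maf) == 800

    def test_row_count_conserved_with_drivers(self):
        cfg = SimulationConfig(seed=5, n_genes=100, n_samples=50,
                               n_total_mutations=800,
                               driver_spec=[(0, 10.0, 0.1)])
        maf, _, _ = simulate_maf(cfg)
        assert len(maf) == 800

    def test_driver_rate_boost_and_patient_floor(self):
        cfg = SimulationConfig(seed=6, n_genes=100, n_samples=100,
                               n_total_mutations=2000,
                               driver_spec=[(0, 10.0, 0.10)])
        maf, lengths, truth = simulate_maf(cfg)
        assert truth["drivers"] == [gene_name(0)]
        driver_rows = maf[maf.Hugo_Symbol == gene_name(0)]
        expected_bg = 2000 * lengths.iloc[0] / lengths.sum()
        assert len(driver_rows) > 3 * expected_bg
        patients = driver_rows.Tumor_Sample_Barcode.str.slice(0, 12).nunique()
        assert patients >= 10

    def test_synonymous_fraction_zero_means_no_silent(self):
        cfg = SimulationConfig(seed=5, n_genes=50, n_samples=30,
                               n_total_mutations=300, synonymous_fraction=0.0)
        maf, _, _ = simulate_maf(cfg)
        assert (maf.Variant_Classification == "Silent").sum() == 0

    def test_determinism(self):
        cfg = SimulationConfig(seed=8, n_genes=60, n_samples=40,
                               n_total_mutations=400)
        maf1, len1, _ = simulate_maf(cfg)
        maf2, len2, _ = simulate_maf(cfg)
        pd.testing.assert_frame_equal(maf1, maf2)
        pd.testing.assert_series_equal(len1, len2)


class TestPpi:
    def test_background_scores_below_cutoff(self):
        cfg = SimulationConfig(seed=4, n_genes=100)
        edges = simulate_ppi(cfg)
        assert edges.combined_score.between(150, 699).all()

    def test_planted_edges_present_at_score(self):
        cfg = SimulationConfig(seed=4, n_genes=100,
                               planted_neighbor_edges=[(0, 50, 850)])
        edges = simulate_ppi(cfg)
        planted = edges[(edges.gene_a == gene_name(0)) & (edges.gene_b == gene_name(50))]
        assert list(planted.combined_score) == [850]

    def test_determinism(self):
        cfg = SimulationConfig(seed=4, n_genes=80)
        pd.testing.assert_frame_equal(simulate_ppi(cfg), simulate_ppi(cfg))


class TestDrugTable:
    def test_planted_drug_exact_targets(self):
        cfg = SimulationConfig(seed=4, n_genes=50, n_drugs=20,
                               planted_drugs=[("MIRACLE", [1, 2, 3])])
        table, truth = simulate_drug_table(cfg)
        got = set(table[table.drug_name == "MIRACLE"].gene)
        assert got == {gene_name(i) for i in (1, 2, 3)}
        assert truth["planted_drugs"] == ["MIRACLE"]

    def test_decoy_target_sizes_within_range(self):
        cfg = SimulationConfig(seed=4, n_genes=50, n_drugs=30,
                               targets_per_drug_range=(2, 5))
        table, _ = simulate_drug_table(cfg)
        sizes = table.groupby("drug_id").gene.nunique()
        assert sizes.between(2, 5).all()

    def test_determinism(self):
        cfg = SimulationConfig(seed=4, n_genes=50, n_drugs=10)
        t1, _ = simulate_drug_table(cfg)
        t2, _ = simulate_drug_table(cfg)
        pd.testing.assert_frame_equal(t1, t2)


class TestAbstracts:
    def test_mention_counts_match_config(self):
        cfg = SimulationConfig(seed=4, n_genes=50, n_abstracts=100,
                               planted_gene_mentions={3: 4, 9: 2})
        records, truth = simulate_abstracts(cfg)
        text = [r for r in records if gene_name(3) in r["abstract"]]
        assert len({r["pmid"] for r in text}) == 4
        assert truth["mentions"] == {gene_name(3): 4, gene_name(9): 2}

    def test_pre_cutoff_years_present(self):
        cfg = SimulationConfig(seed=4, n_genes=10, n_abstracts=200,
                               abstract_year_range=(1995, 2024))
        records, _ = simulate_abstracts(cfg)
        years = [r["year"] for r in records if r["abstract"]]
        assert min(years) < 2001

    def test_determinism(self):
        cfg = SimulationConfig(seed=4, n_genes=10, n_abstracts=50)
        assert simulate_abstracts(cfg) == simulate_abstracts(cfg)


class TestWholeBundle:
    def test_truth_covers_all_stages(self, demo_data):
        truth = demo_data["truth"]
        for key in ("amplified", "deleted", "drivers", "planted_drugs",
                    "planted_targets", "planted_neighbors", "mentions"):
            assert key in truth
        assert len(truth["amplified"]) == 10
        assert len(truth["deleted"]) == 5
        assert len(truth["drivers"]) == 5
        assert len(truth["planted_drugs"]) == 2

    def test_write_inputs_round_trip(self, tmp_path):
        from redrug import io as io_mod

        cfg = demo_config(seed=2, n_genes=40, n_samples=20, n_drugs=10,
                          n_abstracts=60, n_total_mutations=300,
                          amp_spec=[(0, 6, 0.3)], del_spec=[], driver_spec=[],
                          planted_neighbor_edges=[(0, 30, 800)],
                          planted_drugs=[("P", [0])],
                          planted_gene_mentions={0: 2, 30: 2})
        data = write_inputs(cfg, tmp_path)
        cnv = io_mod.read_cnv_long(tmp_path / "cnv.tsv")
        pd.testing.assert_frame_equal(
            cnv, data["cnv"], check_dtype=False
        )
        maf = io_mod.read_maf(tmp_path / "mutations.maf")
        assert len(maf) == 300
        lengths = io_mod.read_gene_lengths(tmp_path / "gene_lengths.tsv")
        pd.testing.assert_series_equal(lengths, data["lengths"],
                                       check_names=False)
        drugs = io_mod.read_drug_table(tmp_path / "drug_gene.csv")
        assert set(drugs.columns) >= {"drug_id", "drug_name", "gene"}
        abstracts = io_mod.read_abstracts(tmp_path / "abstracts.jsonl")
        assert len(abstracts) == len(data["abstracts"])
        lexicon = io_mod.read_lexicon(tmp_path / "lexicon.txt")
        assert lexicon == set(cfg.gene_names)
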