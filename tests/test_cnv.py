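"""Copy-number event calling, scoring and risk-gene selection."""

import numpy as np
import pandas as pd
import pytest

from redrug import cnv
from redrug.stats import bh_fdr

from conftest import long_cnv, multi_gene_cnv


class TestEventCalling:
    def test_amplification_threshold(self):
        stats = cnv.call_cnv_events(long_cnv([5, 2, 2]), "amplification")
        assert stats.loc["G1", "high_event_count"] == 1
        assert stats.loc["G1", "n_samples"] == 3

    def test_diploid_contributes_nothing(self):
        for direction in ("amplification", "deletion"):
            stats = cnv.call_cnv_events(long_cnv([2, 2, 2]), direction)
            assert stats.loc["G1", "high_event_count"] == 0
            assert stats.loc["G1", "amplitude_sum"] == 0.0

    def test_amplitude_capped_at_seven(self):
        stats = cnv.call_cnv_events(long_cnv([9, 2]), "amplification")
        assert stats.loc["G1", "amplitude_sum"] == pytest.approx(np.log2(7) - 1)

    def test_deletion_intensity_accumulation(self):
        # +2 for CNV = 0, +1 for CNV = 1
        stats = cnv.call_cnv_events(long_cnv([0, 1, 1, 2]), "deletion")
        assert stats.loc["G1", "amplitude_sum"] == pytest.approx(4.0)
        assert stats.loc["G1", "high_event_count"] == 1  # only CNV = 0

    def test_high_amplitude_gate_flag(self):
        stats = cnv.call_cnv_events(
            long_cnv([3, 6, 2]), "amplification", amplitude_gate="high"
        )
        # only the CNV = 6 sample contributes under the strict gate
        assert stats.loc["G1", "amplitude_sum"] == pytest.approx(np.log2(6) - 1)

    def test_rejects_non_integer_and_negative(self):
        with pytest.raises(ValueError):
            cnv.call_cnv_events(long_cnv([2.5, 2]), "amplification")
        with pytest.raises(ValueError):
            cnv.call_cnv_events(long_cnv([-1, 2]), "deletion")
        with pytest.raises(ValueError):
            cnv.call_cnv_events(long_cnv([2, 2]), "sideways")


class TestBackgroundRate:
    def test_pooled_rates(self):
        pool = np.array([2, 2, 5, 7, 2, 0, 2, 2, 1, 2])
        assert cnv.background_rate(pool, "amplification") == pytest.approx(0.2)
        assert cnv.background_rate(pool, "deletion") == pytest.approx(0.1)

    def test_all_diploid_is_zero(self):
        assert cnv.background_rate(np.full(50, 2), "amplification") == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cnv.background_rate(np.array([]), "amplification")


class TestGisticLikeScore:
    def test_amplification_worked_example(self):
        stats = cnv.call_cnv_events(long_cnv([6, 6] + [2] * 8), "amplification")
        score = cnv.gistic_like_score(stats, "amplification")
        assert score[0] == pytest.approx((np.log2(6) - 1) * 20.0, abs=1e-6)
        assert score[0] == pytest.approx(31.70, abs=0.005)

    def test_deletion_worked_example(self):
        stats = cnv.call_cnv_events(long_cnv([0, 1] + [2] * 8), "deletion")
        score = cnv.gistic_like_score(stats, "deletion")
        assert score[0] == pytest.approx(15.0)

    def test_all_diploid_scores_zero(self):
        for direction in ("amplification", "deletion"):
            stats = cnv.call_cnv_events(long_cnv([2] * 10), direction)
            assert cnv.gistic_like_score(stats, direction)[0] == 0.0

    def test_score_increases_with_extra_event(self):
        base = cnv.call_cnv_events(long_cnv([6, 6] + [2] * 8), "amplification")
        more = cnv.call_cnv_events(long_cnv([6, 6, 6] + [2] * 7), "amplification")
        assert (
            cnv.gistic_like_score(more, "amplification")[0]
            > cnv.gistic_like_score(base, "amplification")[0]
        )


class TestSignificanceTests:
    def test_binomial_reference(self):
        stats = cnv.call_cnv_events(long_cnv([5, 5] + [2] * 8), "amplification")
        p = cnv.cnv_binomial_test(stats, 0.1)
        assert p[0] == pytest.approx(1 - (0.9**10 + 10 * 0.1 * 0.9**9), abs=1e-12)

    def test_zero_events_give_one(self):
        stats = cnv.call_cnv_events(long_cnv([2] * 10), "amplification")
        assert cnv.cnv_binomial_test(stats, 0.1)[0] == 1.0
        p, _ = cnv.cnv_permutation_test(
            stats, np.full(100, 2), 10, "amplification", 500, seed=0
        )
        assert p[0] == 1.0

    def test_tail_monotone_in_event_count(self):
        df = multi_gene_cnv(
            np.column_stack([[6] * 4 + [2] * 6, [6] * 2 + [2] * 8])
        )
        stats = cnv.call_cnv_events(df, "amplification")
        p = cnv.cnv_binomial_test(stats, 0.05)
        assert p[list(stats.index).index("G0")] <= p[list(stats.index).index("G1")]

    def test_permutation_determinism(self):
        rng = np.random.default_rng(11)
        pool = rng.choice([0, 1, 2, 5, 6], p=[0.05, 0.05, 0.8, 0.05, 0.05], size=2000)
        stats = cnv.call_cnv_events(long_cnv([6, 6, 6] + [2] * 17), "amplification")
        p1, null1 = cnv.cnv_permutation_test(stats, pool, 20, "amplification", 1000, 5)
        p2, null2 = cnv.cnv_permutation_test(stats, pool, 20, "amplification", 1000, 5)
        assert np.array_equal(p1, p2)
        assert np.array_equal(null1.counts, null2.counts)

    def test_permutation_agrees_with_binomial_on_iid_pool(self):
        # both tests estimate the same null when the pool is iid
        rng = np.random.default_rng(2)
        pool = rng.choice([2, 6], p=[0.9, 0.1], size=50_000)
        n, x, n_perm = 100, 16, 4000
        stats = cnv.call_cnv_events(
            long_cnv([6] * x + [2] * (n - x)), "amplification"
        )
        p_binom = cnv.cnv_binomial_test(
            stats, cnv.background_rate(pool, "amplification")
        )[0]
        p_emp, _ = cnv.cnv_permutation_test(
            stats, pool, n, "amplification", n_perm, seed=3
        )
        se = np.sqrt(p_binom * (1 - p_binom) / n_perm)
        assert abs(p_emp[0] - p_binom) <= 3 * se + 1 / (n_perm + 1)


class TestSelectRiskGenes:
    @staticmethod
    def frame(qb, qe, score):
        return pd.DataFrame(
            {
                "q_binomial": qb,
                "q_empirical": qe,
                "gistic_like_score": score,
            },
            index=[f"G{i}" for i in range(len(qb))],
        )

    def test_dual_gate_requires_both(self):
        stats = self.frame([0.01, 0.01], [0.2, 0.01], [50.0, 50.0])
        picked = cnv.select_risk_genes(stats, cutoff_param=0)
        assert picked.genes == {"G1"}

    def test_percentile_cutoff_top_five_of_hundred(self):
        scores = list(range(1, 101))
        stats = self.frame([0.01] * 100, [0.01] * 100, scores)
        picked = cnv.select_risk_genes(stats, cutoff_param=95)
        assert len(picked.genes) == 5
        assert {int(stats.loc[g, "gistic_like_score"]) for g in picked.genes} == {
            96, 97, 98, 99, 100,
        }

    def test_single_dual_significant_gene_retained(self):
        # degenerate distribution: with the cutoff taken over the significant
        # genes' own scores, the lone survivor is always kept
        stats = self.frame([0.01, 0.5], [0.01, 0.5], [5.0, 100.0])
        for method in ("percentile", "knee"):
            picked = cnv.select_risk_genes(
                stats, cutoff_method=method, cutoff_scope="significant"
            )
            assert "G0" in picked.genes

    def test_no_dual_significant_warns_and_returns_empty(self):
        stats = self.frame([0.5, 0.9], [0.5, 0.9], [1.0, 2.0])
        with pytest.warns(UserWarning):
            picked = cnv.select_risk_genes(stats)
        assert picked.genes == set()

    def test_knee_separates_bulk_from_tail(self):
        scores = [1.0] * 50 + [80.0, 90.0, 100.0]
        stats = self.frame([0.01] * 53, [0.01] * 53, scores)
        picked = cnv.select_risk_genes(stats, cutoff_method="knee")
        assert picked.genes == {"G50", "G51", "G52"}


class TestNullCalibration:
    def test_fully_null_stratum_rarely_passes_dual_gate(self, null_cnv):
        stats = cnv.analyze_cnv(null_cnv, "amplification",
                                n_permutations=1000, seed=7)
        dual = (stats["q_binomial"] < 0.05) & (stats["q_empirical"] < 0.05)
        assert dual.mean() <= 0.05


class TestPlantedRecovery:
    def test_planted_amplifications_recovered(self, demo_data):
        stats = cnv.analyze_cnv(demo_data["cnv"], "amplification",
                                n_permutations=10_000, seed=1)
        picked = cnv.select_risk_genes(stats)
        planted = set(demo_data["truth"]["amplified"])
        assert planted <= picked.genes
        assert len(picked.genes - planted) <= 2
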