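"""Call amplification risk genes from a copy-number cohort.

Each gene's high-level event count (CNV > 4) is tested against the cohort's
genome-wide background rate (binomial) and a resampled null (permutation);
dual-significant genes are ranked by the GISTIC-like amplitude x frequency
score and thresholded at the 95th percentile of the score distribution.
"""

from redrug import cnv, simulate

data = simulate.simulate_all(simulate.demo_config(seed=1))

stats = cnv.analyze_cnv(data["cnv"], "amplification",
                        n_permutations=10_000, seed=1)
print(f"background amplification rate: {stats.attrs['background_rate']:.4f}")
# (fraction of all gene x sample observations with CNV > 4)

risk = cnv.select_risk_genes(stats)
print(f"score cutoff ({risk.selection_method}): {risk.score_cutoff:.2f}")
print(f"risk genes: {sorted(risk.genes)}")

planted = set(data["truth"]["amplified"])
print(f"recovered {len(risk.genes & planted)}/{len(planted)} planted genes, "
      f"{len(risk.genes - planted)} false positives")

top = stats.loc[sorted(risk.genes)].sort_values("gistic_like_score",
                                                ascending=False)
cols = ["high_event_count", "event_frequency_pct", "q_binomial",
        "q_empirical", "gistic_like_score"]
print(top[cols].head(10).to_string())
# q_* are BH-adjusted p-values; the score multiplies mean log2 amplitude
# above diploid by the percent of samples with a high-level event.
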