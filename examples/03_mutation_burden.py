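"""Find significantly mutated genes after CDS-length normalization.

Longer genes accumulate more mutations by chance, so each gene's
non-synonymous count is tested against p = L_gene / sum(L) under a binomial
and a multinomial permutation null; MutationScore = (mutations per bp) x
(percent of patients mutated) ranks the survivors.
"""

import pandas as pd

from redrug import cnv, simulate, somatic

data = simulate.simulate_all(simulate.demo_config(seed=1))
maf = data["maf"]
frame = pd.DataFrame(
    {
        "gene": maf.Hugo_Symbol,
        "variant_classification": maf.Variant_Classification,
        "sample_id": somatic.truncate_to_patient(maf.Tumor_Sample_Barcode),
    }
)

stats = somatic.analyze_som(frame, data["lengths"], cohort_size=100,
                            n_simulations=10_000, seed=1)
print(f"total mutations (incl. synonymous): {stats.attrs['n_total_mutations']}")
print(f"genes with >=1 non-synonymous mutation: {len(stats)}")

risk = cnv.select_risk_genes(stats, "mutation_score")
print(f"significantly mutated genes: {sorted(risk.genes)}")
planted = set(data["truth"]["drivers"])
print(f"recovered {len(risk.genes & planted)}/{len(planted)} planted drivers")

cols = ["mutation_count", "cds_length", "frequency_pct",
        "q_binomial", "q_empirical", "mutation_score"]
print(stats.loc[sorted(risk.genes), cols].to_string())
# mutation_score units: (mutations/bp) x percent of cohort mutated.
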