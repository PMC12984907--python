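"""Run the full HPV-stratified workflow end to end on the demo cohort.

Per stratum: copy-number and mutation risk genes -> PPI expansion ->
literature validation -> drug enrichment, then the per-source summary table
and the final candidate drugs.
"""

from redrug import pipeline, simulate

config = simulate.demo_config(seed=1)  # 30% HPV-positive, 70% negative
data = simulate.simulate_all(config)

params = pipeline.PipelineParams(
    cnv_permutations=10_000,   # demo-scale resolution (see docs/methods.md)
    som_simulations=10_000,
    drug_permutations=10_000,
    seed=1,
)
results = pipeline.run_full(data, params)

print(pipeline.report_summary(results).to_string(index=False))
# One row per stratum x alteration source: risk genes, how many are drug
# targets, PPI neighbors, drug-annotated genes, and drugs passing both
# enrichment tests for that source's risk set.

for stratum, res in results.items():
    dr = res.drug_results
    retained = dr[dr.retained] if len(dr) else dr
    print(f"\n{stratum}: {len(retained)} candidate drugs from the union risk set")
    if len(retained):
        cols = ["drug_name", "x", "q_hypergeom", "q_empirical", "classification"]
        print(retained[cols].head(5).to_string(index=False))
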