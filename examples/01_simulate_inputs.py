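"""Generate the demo synthetic cohort and inspect what was planted.

The generator writes every input the pipeline consumes — copy-number table,
MAF, gene lengths, HPV labels, PPI edges, drug–gene interactions, abstracts —
with known ground truth, so downstream stages can be scored exactly.
"""

from redrug import simulate

config = simulate.demo_config(seed=1)
data = simulate.simulate_all(config)

print(f"cohort: {config.n_genes} genes x {config.n_samples} samples")
print(f"CNV rows: {len(data['cnv'])}, MAF rows: {len(data['maf'])}")
print(f"PPI edges: {len(data['ppi'])}, drug-gene rows: {len(data['drugs'])}")
print(f"abstracts: {len(data['abstracts'])}")
truth = data["truth"]
print("planted amplified genes:", truth["amplified"])
print("planted deleted genes:  ", truth["deleted"])
print("planted mutation drivers:", truth["drivers"])
print("planted drugs:", truth["planted_drugs"])
# Every listed gene/drug is recoverable signal; everything else is background
# noise drawn from the null distributions each test assumes.
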