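# Methods

## Model and procedure

The pipeline treats a tumor cohort as a matrix of integer gene-level copy
numbers (diploid baseline 2) and a list of somatic mutations, both
partitioned by HPV status before any statistics are computed — strata are
never pooled, because amplification/deletion/mutation landscapes differ
between HPV-positive and HPV-negative disease. Within a stratum the question
asked of every gene is the same: does its alteration count exceed what the
cohort's own background process would produce?

### Copy-number events

High-level amplification is CNV > 4; high-level deletion is CNV = 0. With
integer copy numbers "CNV < 1" and "CNV = 0" coincide, which is why the
ingest layer rejects non-integer copy numbers rather than silently rounding.

Two tests per gene and direction:

1. **Binomial.** x = high-level events among n samples, against
   p_null = (# observations beyond the threshold) / (all gene × sample
   observations in the stratum). This conditions on the cohort's overall
   instability: a cohort riddled with amplifications needs a higher per-gene
   count to be surprising.
2. **Permutation.** One null per stratum × direction: each permutation draws
   n values with replacement from the pooled observations and counts
   threshold exceedances. The null is built once and reused for every gene
   (it does not depend on the gene), and the empirical p-value is add-one
   smoothed: p = (1 + #{count_i ≥ x}) / (N + 1), with ties counting as
   exceedances. Its floor is 1/(N+1); it can never be 0.

Both p-vectors get Benjamini–Hochberg adjustment; a gene must clear q < α in
**both** tests (dual gating) before scoring.

**Composite score.** Amplification amplitude per altered sample (CNV > 2) is
log2(min(CNV, 7)) − 1 — zero at diploid, capped at 7 copies so one extreme
outlier cannot outrank frequent moderate amplification. Deletion intensity is
+1 for single-copy loss and +2 for homozygous loss, accumulated over samples
with CNV < 2. The score is mean amplitude × percent frequency of high-level
events (for deletions, frequency of CNV = 0). Two readings of the amplitude
rule are defensible — log2(CNV) − 1 and log2(CNV − 1) both vanish at diploid —
and both are implemented (`score_convention`); the default is log2(CNV) − 1
because it is the standard log-ratio-to-diploid convention and stays finite
at CNV = 1. Which samples enter the amplitude average is likewise
configurable (`amplitude_gate`): the default averages over all altered
samples (CNV > 2 / CNV < 2), keeping the amplitude independent of cohort
size; the alternative restricts to high-level events.

**Selection.** Dual-significant genes with score at or above a
distribution-based cutoff are the risk genes. The default cutoff is the 95th
percentile of the score distribution over **all** genes in the stratum ×
direction (`cutoff_scope="all"`); taking the percentile only over the
dual-significant genes (`"significant"`) is available but degenerates when
few genes are significant — the 95th percentile of ten near-equal scores
retains only the top one or two, which defeats the purpose of the score gate
as a refinement of the significance gate. A knee detector (maximum
perpendicular distance from the chord of the descending score curve, cutoff
midway between the knee point and its upper neighbor) is provided for
distributions with a clear bulk/tail break.

### Somatic mutations

Mutations are filtered to non-synonymous classes (missense, nonsense,
frameshifts, in-frame indels, splice/translation-start/nonstop); the total
count N, however, includes synonymous events — they calibrate the background
rate without contributing signal. Sample barcodes are truncated to the
12-character patient prefix so multiple aliquots of one patient count once.

Per gene: x non-synonymous events are tested under Binomial(N, L_gene / Σ L)
with L the CDS length and the sum running over the full annotation universe,
and against a Multinomial(N, p) permutation null simulated over the same
universe (counts conserved within every draw). A per-gene
Binomial(N, p_j)-marginal shortcut (`method="binomial"`) is distributionally
identical per gene and cheaper for very large universes; the test suite
checks the two routes agree within 3 Monte-Carlo standard errors.
MutationScore = (x / L) × (percent of patients mutated); the percent scale
matches the copy-number score, and since it is a global constant factor the
gene ranking is unaffected by the proportion-vs-percent choice. Genes mutated
in the MAF but absent from the annotation are excluded from testing and
logged.

### Network expansion

Risk genes are expanded one hop through PPI edges with combined score ≥ 700
(the conventional high-confidence band; the strict ">" variant is a flag and
differs only for edges scoring exactly 700). Seeds never become neighbors.
The expansion keeps neighbor → {seeds} provenance, which later distinguishes
"indirect" drug candidates and feeds the drug → target → risk-gene Sankey
table. No per-seed top-k is applied by default (`max_neighbors` exists), and
no multi-hop or diffusion scoring is attempted.

### Literature validation

Abstract records are cleaned — empty abstracts, unparseable or pre-2001
years ("past 25 years"), duplicate PMIDs dropped, with per-reason counts —
then passed to a target-extraction backend. The shipped backend is a
deterministic lexicon matcher: sentences are segmented on terminal
punctuation with abbreviation guards, gene symbols match whole tokens
case-sensitively, and the evidence sentence is stored verbatim (an invariant
the pipeline enforces on any backend: the sentence must round-trip to a
substring of the abstract and contain the gene as a token). Large-language-
model extraction is deliberately out of scope; the backend protocol is the
seam where such a service would plug in. A candidate gene is validated when
≥ `min_articles` distinct PMIDs supply evidence (default 1 — the evidence
bar is intentionally the weakest defensible one, and the support map is
emitted so stricter thresholds can be applied post hoc). Validation is
applied with the same criterion to direct risk genes and to neighbors,
configurable separately.

### Drug enrichment

The druggable universe M is every gene with at least one interaction in the
drug–gene table; the risk set n is (validated direct risk genes ∪ validated
neighbors) ∩ universe. Per drug: x = |targets ∩ risk set| is scored with the
right-tailed hypergeometric tail and with an empirical test that samples
gene sets of size n uniformly without replacement from the universe —
one sampled set per permutation, shared across all drugs, exactly the
resampling scheme the empirical test describes (implemented in vectorized
chunks; the subset is the n smallest of M iid uniforms). BH runs across all
drugs separately per test; dual q < α retains a drug. Classification is a
property of the retained drug's overlap: direct / indirect / both. Drugs
with x = 0 stay in the output (p = 1) for audit but can never be retained.

### Orchestration

`pipeline.run_full` stratifies samples, runs both CNV directions and the
mutation analysis per stratum, then performs expansion → validation →
enrichment twice: once per alteration source (feeding the six-row summary
table: high-risk genes, risk genes available as drug targets, immediate
neighbors, drug-annotated genes, significant medications) and once on the
union of the three risk-gene sets (the stratum's final candidate list and
Sankey edges). Every stochastic stage derives its seed deterministically
from the run seed and the stage labels, so a fixed configuration reproduces
byte-identical outputs; dropped-record counts (unlabeled samples,
unannotated genes, dirty abstracts, unmappable PPI endpoints) are logged at
every stage.

## Parameter defaults

| parameter | default | units / rationale |
|---|---|---|
| amplification threshold | CNV > 4 | high-level events only |
| deletion threshold | CNV = 0 | homozygous loss (integer CNV) |
| amplitude cap | 7 copies | outlier control in the score |
| CNV permutations | 1000 | paper-scale cohorts (tens of thousands of genes); see resolution note |
| mutation-null simulations | 10,000 | sparse counts need finer resolution |
| drug permutations | 100,000 | p-floor 1e-5 for small candidate sets |
| PPI combined score | ≥ 700 | high-confidence band (scores 0–1000) |
| FDR level α | 0.05 | per test, dual-gated |
| abstract year cutoff | ≥ 2001 | "past 25 years" |
| min supporting articles | 1 | weakest defensible evidence bar |
| score cutoff | 95th percentile, all genes | `knee` optional |

**Permutation resolution.** An add-one empirical p has floor 1/(N+1), so
after BH over m genes the smallest achievable q for k genes tied at the
floor is m/(k(N+1)). This must be < α or the dual gate can never pass: with
m = 500 genes and k = 5 true signals, N = 1000 gives a floor of ≈ 0.1 —
structurally above α = 0.05 — while N = 10,000 gives ≈ 0.01. Demo-scale
analyses therefore use 10,000 CNV permutations; 1000 suffices for
paper-scale inputs where thousands of genes share the floor. The same
arithmetic sets the 10,000 mutation simulations and 100,000 drug
permutations.

## The synthetic cohorts

The generator emulates the *statistical shape* the tests assume, not real
tumor biology: background copy numbers are iid over {0..7} with ≈ 98% mass
at diploid and ≈ 0.4% at each other level (so background rates are
non-degenerate); planted genes take a fixed level in a fixed carrier
fraction (exact count, deterministic rounding); mutations scatter
length-proportionally with multiplicative driver boosts and a guaranteed
per-driver patient floor (short-drawn drivers are topped up and the surplus
removed from the most-mutated background genes, conserving the total);
background PPI edges score strictly below 700 so high-confidence neighbors
are exactly the planted ones; decoy drugs draw uniform target sets; planted
abstracts always carry post-cutoff years. The default demo: 500 genes × 100
samples, 10 amplified (CNV 6 in 30%), 5 deleted (CNV 0 in 30%), 5 drivers
(10× rate, ≥ 10% of patients), 2 planted neighbors per risk gene at score
850, 200 drugs with 2 planted, 500 abstracts — the full run takes a few
seconds.

What passing these tests shows: the statistics are implemented correctly
(oracle agreement), calibrated (null cohorts yield ~0 dual-significant
calls), and powerful enough to recover stylized signal. What it does not
show: behavior under correlated copy-number segments, arm-level events,
mutation hotspots/signatures, scale-free PPI topology, promiscuous drug
target profiles, or free-text abstracts — real data carry all of these, and
the thresholds that recover planted signal cleanly here will trade
sensitivity for specificity differently there. One stochastic edge is worth
knowing: a driver gene with a very short CDS (< 1 kb) at a 10× rate boost
sits near the detection boundary of the binomial test in a 500-gene cohort,
so demo-cohort driver recovery can drop to 3/5 at some seeds even though
the dedicated 300-gene driver fixture recovers 5/5 at every seed tested.

## Numerical choices and degenerate inputs

- Binomial and hypergeometric tails go through survival functions
  (scipy), never naive summation; x ≤ 0 returns 1, x > n returns 0.
- Empirical p-values count ties as exceedances and are add-one smoothed on
  both sides of the fraction.
- Scores of genes with no altered samples are exactly 0 (no 0/0).
- An empty dual-significant set yields an empty risk set with a warning,
  not an error; an empty stratum is skipped with a zero-filled summary row.
- Extraction backends that fail on > 50% of records abort the run; isolated
  failures skip the record and log.
- The knee cutoff falls back to "retain all" when fewer than 3 scores or a
  flat distribution make a knee meaningless.

## Known limitations

No segment-level CNV calling, GC correction, or true GISTIC peel-off; no
covariate-aware mutation background (expression, replication timing,
trinucleotide context); no multi-hop network propagation; no entity
normalization beyond the lexicon; no DrugBank XML parsing (flat interaction
exports only); no action-type weighting in enrichment. The literature stage
validates gene–disease support only — drug co-mentions are carried as
annotation, not used as a filter.
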