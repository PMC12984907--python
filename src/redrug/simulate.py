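"""Synthetic cohort generator with planted, recoverable signal.

Emulates every input the pipeline consumes — gene-level copy-number tables,
MAF somatic mutations with CDS lengths, HPV status labels, scored PPI edges,
drug–gene interactions and abstract corpora — with known ground truth, so
each stage and the end-to-end run can be tested without any download.

The signal is stylized rather than matched to any real tumor cohort: planted
amplified/deleted genes take a fixed copy-number level in a fixed fraction of
carriers, mutation drivers get a multiplicative rate boost over the
length-proportional background, planted PPI edges sit above the
high-confidence cutoff while background edges sit below it, and planted drugs
target planted risk genes.  Every generator is a pure function of its
configuration (including the seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "demo_config",
    "gene_name",
    "simulate_cnv_cohort",
    "simulate_labels",
    "simulate_maf",
    "simulate_ppi",
    "simulate_drug_table",
    "simulate_abstracts",
    "simulate_all",
    "write_inputs",
]

#: default integer copy-number background: ~98% diploid with ~0.4% mass on
#: each non-diploid level so background-rate estimation is non-degenerate
DEFAULT_CNV_BACKGROUND = {0: 0.004, 1: 0.004, 2: 0.972, 3: 0.004, 4: 0.004,
                          5: 0.004, 6: 0.004, 7: 0.004}


@dataclass
class SimulationConfig:
    """All knobs for the synthetic cohort; see :func:`demo_config` for the
    standard demo settings."""

    seed: int = 0
    n_genes: int = 500
    n_samples: int = 100
    hpv_positive_fraction: float = 0.3
    # (gene index, copy-number level, carrier fraction)
    amp_spec: list = field(default_factory=list)
    del_spec: list = field(default_factory=list)
    background_cnv_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_CNV_BACKGROUND)
    )
    # (gene index, rate multiplier, min patient fraction)
    driver_spec: list = field(default_factory=list)
    synonymous_fraction: float = 0.3
    n_total_mutations: int = 2000
    gene_length_range: tuple = (500, 5000)
    ppi_density: float = 0.01
    # (seed gene index, neighbor gene index, combined score)
    planted_neighbor_edges: list = field(default_factory=list)
    n_drugs: int = 200
    targets_per_drug_range: tuple = (2, 8)
    # (drug name, list of target gene indices)
    planted_drugs: list = field(default_factory=list)
    n_abstracts: int = 500
    # gene index -> number of supporting abstracts
    planted_gene_mentions: dict = field(default_factory=dict)
    abstract_year_range: tuple = (1995, 2024)
    empty_abstract_fraction: float = 0.04
    duplicate_pmid_fraction: float = 0.02

    def __post_init__(self) -> None:
        for name in ("hpv_positive_fraction", "synonymous_fraction",
                     "ppi_density", "empty_abstract_fraction",
                     "duplicate_pmid_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        planted = (
            [i for i, _, _ in self.amp_spec]
            + [i for i, _, _ in self.del_spec]
            + [i for i, _, _ in self.driver_spec]
            + [i for pair in self.planted_neighbor_edges for i in pair[:2]]
            + [i for _, idxs in self.planted_drugs for i in idxs]
            + list(self.planted_gene_mentions)
        )
        if planted and max(planted) >= self.n_genes:
            raise ValueError("planted gene index exceeds n_genes")
        total = sum(self.background_cnv_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError("background CNV distribution must sum to 1")

    @property
    def gene_names(self) -> list:
        return [gene_name(i) for i in range(self.n_genes)]

    @property
    def sample_ids(self) -> list:
        return [f"TCGA-SY-{j:04d}" for j in range(self.n_samples)]


def gene_name(i: int) -> str:
    return f"GENE{i:04d}"


def demo_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The standard demo cohort: 500 genes x 100 samples with planted signal.

    10 amplified genes (CNV 6 in 30% of samples), 5 deleted genes (CNV 0 in
    30%), 5 mutation drivers (10x the length-expected rate, each hitting at
    least 10% of patients), 2 planted high-confidence PPI neighbors per
    planted risk gene, 200 drugs of which 2 target only planted risk
    genes/neighbors, and 500 abstracts mentioning every planted gene.
    """
    amp = [(i, 6, 0.30) for i in range(10)]
    dele = [(i, 0, 0.30) for i in range(10, 15)]
    drivers = [(i, 10.0, 0.10) for i in range(15, 20)]
    risk_idx = [i for i, _, _ in amp + dele + drivers]
    neighbor_edges = []
    neighbor_idx = []
    for k, i in enumerate(risk_idx):
        for j in range(2):
            nb = 400 + 2 * k + j
            neighbor_edges.append((i, nb, 850))
            neighbor_idx.append(nb)
    planted_drugs = [
        # direct: targets planted risk genes themselves
        ("PLANTED-DIRECT", risk_idx[:5]),
        # indirect: targets planted neighbors only
        ("PLANTED-INDIRECT", neighbor_idx[:5]),
    ]
    mentions = {i: 3 for i in risk_idx + neighbor_idx}
    cfg = dict(
        seed=seed,
        amp_spec=amp,
        del_spec=dele,
        driver_spec=drivers,
        planted_neighbor_edges=neighbor_edges,
        planted_drugs=planted_drugs,
        planted_gene_mentions=mentions,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # independent, reproducible stream per generator (hash() is salted per
    # process, so derive the stream key from the bytes instead)
    stream_key = int.from_bytes(stream.encode(), "big") % (2**31)
    return np.random.default_rng([config.seed, stream_key])


def simulate_labels(config: SimulationConfig) -> pd.DataFrame:
    """HPV status per sample; deterministic positive count = round(frac * n)."""
    rng = _rng(config, "labels")
    n_pos = int(round(config.hpv_positive_fraction * config.n_samples))
    pos = set(rng.choice(config.n_samples, size=n_pos, replace=False))
    return pd.DataFrame(
        {
            "sample_id": config.sample_ids,
            "hpv_status": [
                "positive" if j in pos else "negative"
                for j in range(config.n_samples)
            ],
        }
    )


def simulate_cnv_cohort(config: SimulationConfig):
    """Long-format copy-number table plus ground truth.

    Background genes draw iid integer copy numbers from the background
    distribution; each planted gene takes its specified level in exactly
    ``round(fraction * n_samples)`` carrier samples and background values
    elsewhere.
    """
    rng = _rng(config, "cnv")
    levels = np.array(sorted(config.background_cnv_distribution))
    probs = np.array([config.background_cnv_distribution[l] for l in levels])
    matrix = rng.choice(levels, p=probs, size=(config.n_samples, config.n_genes))

    truth = {"amplified": [], "deleted": []}
    for spec, key in ((config.amp_spec, "amplified"), (config.del_spec, "deleted")):
        for idx, level, frac in spec:
            n_carriers = int(round(frac * config.n_samples))
            if n_carriers < 1:
                raise ValueError(
                    f"carrier fraction {frac} yields no carriers for gene {idx}"
                )
            carriers = rng.choice(config.n_samples, size=n_carriers, replace=False)
            matrix[carriers, idx] = level
            truth[key].append(gene_name(idx))

    genes = config.gene_names
    df = pd.DataFrame(
        {
            "sample_id": np.repeat(config.sample_ids, config.n_genes),
            "gene": np.tile(genes, config.n_samples),
            "chromosome": np.tile(
                [f"chr{(i % 22) + 1}" for i in range(config.n_genes)],
                config.n_samples,
            ),
            "start": np.tile(
                [10_000 * (i + 1) for i in range(config.n_genes)], config.n_samples
            ),
            "end": np.tile(
                [10_000 * (i + 1) + 5_000 for i in range(config.n_genes)],
                config.n_samples,
            ),
            "copy_number": matrix.ravel(),
        }
    )
    return df, truth


def simulate_gene_lengths(config: SimulationConfig) -> pd.Series:
    rng = _rng(config, "lengths")
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    return pd.Series(lengths, index=config.gene_names, name="cds_length")


_NONSYN_CLASSES = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del"]
_NONSYN_PROBS = [0.8, 0.1, 0.1]


def simulate_maf(config: SimulationConfig):
    """MAF-style mutation table, CDS lengths and driver ground truth.

    Exactly ``n_total_mutations`` rows are generated.  Events land in genes
    with probability proportional to CDS length times the driver rate
    multiplier; each driver is guaranteed to hit at least its minimum patient
    fraction (events are assigned to distinct patients first).  Each event is
    Silent with probability ``synonymous_fraction``, otherwise a
    non-synonymous class.
    """
    lengths = simulate_gene_lengths(config)
    rng = _rng(config, "maf")
    weights = lengths.to_numpy(dtype=float).copy()
    min_patients = {}
    for idx, mult, min_frac in config.driver_spec:
        weights[idx] *= mult
        min_patients[idx] = int(np.ceil(min_frac * config.n_samples))
    counts = rng.multinomial(config.n_total_mutations, weights / weights.sum())

    # guarantee each driver its minimum patient floor while conserving the
    # total: top up short drivers and remove the surplus from the most
    # mutated non-driver genes
    driver_idx = set(min_patients)
    for idx, needed in sorted(min_patients.items()):
        deficit = needed - counts[idx]
        while deficit > 0:
            donors = [
                j for j in np.argsort(counts)[::-1]
                if j not in driver_idx and counts[j] > 0
            ]
            if not donors:
                raise ValueError("cannot satisfy driver patient floors")
            counts[donors[0]] -= 1
            counts[idx] += 1
            deficit -= 1

    # full barcodes exercise the patient-prefix truncation at ingest
    barcodes = [f"{s}-01A-11D" for s in config.sample_ids]
    rows = []
    for idx in np.nonzero(counts)[0]:
        c = int(counts[idx])
        needed = min_patients.get(idx, 0)
        if needed:
            distinct = rng.choice(config.n_samples, size=needed, replace=False)
            rest = rng.integers(0, config.n_samples, size=c - needed)
            patients = np.concatenate([distinct, rest])
        else:
            patients = rng.integers(0, config.n_samples, size=c)
        syn = rng.random(c) < config.synonymous_fraction
        classes = np.where(
            syn, "Silent", rng.choice(_NONSYN_CLASSES, p=_NONSYN_PROBS, size=c)
        )
        for patient, cls in zip(patients, classes):
            rows.append((gene_name(idx), cls, barcodes[patient]))

    maf = pd.DataFrame(
        rows, columns=["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"]
    )
    maf = maf.sample(frac=1.0, random_state=config.seed).reset_index(drop=True)
    truth = {"drivers": [gene_name(i) for i, _, _ in config.driver_spec]}
    return maf, lengths, truth


def simulate_ppi(config: SimulationConfig) -> pd.DataFrame:
    """Scored PPI edges: sub-threshold background plus planted high-score edges.

    Background edges are Erdős–Rényi with combined scores uniform on
    [150, 699] — always below the 700 cutoff, so the neighbors recoverable at
    high confidence are exactly the planted ones.
    """
    rng = _rng(config, "ppi")
    n = config.n_genes
    n_edges = int(config.ppi_density * n * (n - 1) / 2)
    a = rng.integers(0, n, size=2 * n_edges)
    b = rng.integers(0, n, size=2 * n_edges)
    keep = a < b
    pairs = list(dict.fromkeys(zip(a[keep], b[keep])))[:n_edges]
    planted = {(min(i, j), max(i, j)) for i, j, _ in config.planted_neighbor_edges}
    pairs = [p for p in pairs if p not in planted]
    scores = rng.integers(150, 700, size=len(pairs))
    rows = [
        (gene_name(i), gene_name(j), int(s)) for (i, j), s in zip(pairs, scores)
    ]
    rows += [
        (gene_name(i), gene_name(j), int(score))
        for i, j, score in config.planted_neighbor_edges
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])


def simulate_drug_table(config: SimulationConfig):
    """Drug–gene interactions: uniform decoy target sets plus planted drugs."""
    rng = _rng(config, "drugs")
    lo, hi = config.targets_per_drug_range
    actions = np.array(["inhibitor", "activator", "modulator", "binder"])
    rows = []
    for d in range(config.n_drugs):
        k = int(rng.integers(lo, hi + 1))
        tgt = rng.choice(config.n_genes, size=k, replace=False)
        for g in tgt:
            rows.append(
                (f"DB{d:05d}", f"Decoy-{d}", gene_name(g), str(rng.choice(actions)))
            )
    for name, idxs in config.planted_drugs:
        for g in idxs:
            rows.append((name, name, gene_name(g), "inhibitor"))
    df = pd.DataFrame(rows, columns=["drug_id", "drug_name", "gene", "action"])
    truth = {
        "planted_drugs": [name for name, _ in config.planted_drugs],
        "planted_targets": {
            name: [gene_name(i) for i in idxs] for name, idxs in config.planted_drugs
        },
    }
    return df, truth


_SENTENCE_TEMPLATES = [
    "{gene} was recurrently altered in head and neck tumors.",
    "High {gene} expression correlated with poor prognosis in HNC.",
    "Knockdown of {gene} suppressed proliferation of HNC cell lines.",
]
_FILLER = (
    "Head and neck cancer remains a major clinical challenge. "
    "We analyzed a retrospective patient cohort."
)


def simulate_abstracts(config: SimulationConfig):
    """Abstract corpus with planted gene mentions and deliberate dirty records.

    Planted mentions always carry post-2000 years so they survive the year
    filter; a configurable fraction of additional decoy records have empty
    abstracts, pre-cutoff years or duplicated PMIDs to exercise cleaning.
    """
    rng = _rng(config, "abstracts")
    lo_year, hi_year = config.abstract_year_range
    records = []
    pmid = 10_000_000
    for idx, n_mentions in sorted(config.planted_gene_mentions.items()):
        g = gene_name(idx)
        for _ in range(n_mentions):
            template = _SENTENCE_TEMPLATES[int(rng.integers(len(_SENTENCE_TEMPLATES)))]
            year = int(rng.integers(max(2001, lo_year), hi_year + 1))
            records.append(
                {
                    "pmid": str(pmid),
                    "title": f"A study of {g} in head and neck cancer",
                    "year": year,
                    "abstract": _FILLER + " " + template.format(gene=g),
                }
            )
            pmid += 1
    n_decoy = max(0, config.n_abstracts - len(records))
    n_empty = int(round(config.empty_abstract_fraction * n_decoy))
    n_dup = int(round(config.duplicate_pmid_fraction * n_decoy))
    for d in range(n_decoy):
        year = int(rng.integers(lo_year, hi_year + 1))
        abstract = "" if d < n_empty else _FILLER
        records.append(
            {
                "pmid": str(pmid),
                "title": "An unrelated oncology report",
                "year": year,
                "abstract": abstract,
            }
        )
        pmid += 1
    for d in range(min(n_dup, len(records))):
        dup = dict(records[int(rng.integers(len(records)))])
        records.append(dup)
    truth = {
        "mentions": {
            gene_name(i): m for i, m in sorted(config.planted_gene_mentions.items())
        }
    }
    return records, truth


def simulate_all(config: SimulationConfig) -> dict:
    """Generate every input kind plus a combined ground-truth dictionary."""
    cnv, cnv_truth = simulate_cnv_cohort(config)
    labels = simulate_labels(config)
    maf, lengths, maf_truth = simulate_maf(config)
    ppi = simulate_ppi(config)
    drug_table, drug_truth = simulate_drug_table(config)
    abstracts, abs_truth = simulate_abstracts(config)
    truth = {
        **cnv_truth,
        **maf_truth,
        **drug_truth,
        **abs_truth,
        "planted_neighbors": sorted(
            {gene_name(j) for _, j, _ in config.planted_neighbor_edges}
        ),
    }
    return {
        "cnv": cnv,
        "labels": labels,
        "maf": maf,
        "lengths": lengths,
        "ppi": ppi,
        "drugs": drug_table,
        "abstracts": abstracts,
        "lexicon": config.gene_names,
        "truth": truth,
        "config": config,
    }


def write_inputs(config: SimulationConfig, outdir) -> dict:
    """Write every simulated input in the file format its consumer reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = simulate_all(config)
    data["cnv"].to_csv(outdir / "cnv.tsv", sep="\t", index=False)
    data["labels"].to_csv(outdir / "labels.tsv", sep="\t", index=False)
    data["maf"].to_csv(outdir / "mutations.maf", sep="\t", index=False)
    data["lengths"].rename_axis("gene").reset_index().to_csv(
        outdir / "gene_lengths.tsv", sep="\t", index=False
    )
    data["ppi"].to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    data["drugs"].to_csv(outdir / "drug_gene.csv", index=False)
    with open(outdir / "abstracts.jsonl", "w") as fh:
        for rec in data["abstracts"]:
            fh.write(json.dumps(rec) + "\n")
    (outdir / "lexicon.txt").write_text("\n".join(data["lexicon"]) + "\n")
    cfg = dataclasses.asdict(config)
    cfg["planted_gene_mentions"] = {
        str(k): v for k, v in cfg["planted_gene_mentions"].items()
    }
    cfg["background_cnv_distribution"] = {
        str(k): v for k, v in cfg["background_cnv_distribution"].items()
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"truth": data["truth"], "config": cfg}, fh, indent=2, default=list)
    return data
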