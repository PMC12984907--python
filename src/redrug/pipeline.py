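"""Configuration-driven orchestration of the full repurposing workflow.

Per HPV stratum the pipeline runs: copy-number amplification and deletion
risk-gene calling, somatic-mutation risk-gene calling, PPI neighbor
expansion, literature validation of both risk genes and neighbors, and
drug-target enrichment — then emits a per-source summary table (high-risk
genes, risk genes available as drug targets, immediate neighbors,
drug-annotated genes, significant medications), the ranked drug table with
direct/indirect classification, and a drug -> target -> risk-gene Sankey
edge table.

Per-source counts come from expanding/validating/enriching each alteration
source on its own; the final candidate list comes from the union of the
three risk-gene sets expanded jointly.  Every stochastic stage derives its
own seed deterministically from the run seed, so a fixed configuration
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cnv as cnv_mod
from . import drugs as drugs_mod
from . import io as io_mod
from . import literature as lit_mod
from . import ppi as ppi_mod
from . import somatic as som_mod

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineParams",
    "StratumResult",
    "stratify_samples",
    "run_full",
    "run_from_files",
    "report_summary",
    "write_results",
]

STRATA = ("hpv_positive", "hpv_negative")
CNV_SOURCES = {"cnv_amplification": "amplification", "cnv_deletion": "deletion"}
SOURCES = ("cnv_amplification", "cnv_deletion", "somatic_mutation")


@dataclass
class PipelineParams:
    """Every tunable the workflow exposes, with the standard defaults.

    The defaults mirror the published analysis conventions: high-level CNV
    thresholds >4 / =0 with amplitude cap 7 (encoded in :mod:`redrug.cnv`),
    1000 CNV permutations, 10,000 mutation-null simulations, 100,000 drug
    permutations, STRING combined-score cutoff 700, FDR level 0.05, abstract
    year cutoff 2001, and the 95th-percentile score cutoff.
    """

    alpha: float = 0.05
    cnv_permutations: int = 1000
    som_simulations: int = 10000
    drug_permutations: int = 100000
    ppi_min_score: int = 700
    ppi_strict: bool = False
    min_year: int = 2001
    min_articles: int = 1
    cutoff_method: str = "percentile"
    cutoff_param: float = 95.0
    cutoff_scope: str = "all"
    amplitude_gate: str = "altered"
    score_convention: str = "log2_minus_1"
    som_permutation_method: str = "multinomial"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        params = {k: v for k, v in raw.items() if k in known}
        return cls(**params)


@dataclass
class StratumResult:
    stratum: str
    n_samples: int
    risk_sets: dict = field(default_factory=dict)      # source -> RiskGeneSet
    gene_stats: dict = field(default_factory=dict)     # source -> DataFrame
    per_source: dict = field(default_factory=dict)     # source -> stage dict
    neighbor_map: ppi_mod.NeighborMap | None = None    # union expansion
    validated_direct: lit_mod.ValidatedGeneSet | None = None
    validated_neighbors: lit_mod.ValidatedGeneSet | None = None
    drug_results: pd.DataFrame | None = None           # union enrichment
    sankey_edges: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def stage_seed(base: int, *labels: str) -> int:
    """Deterministic per-stage seed derived from the run seed and stage labels."""
    digest = hashlib.blake2s("/".join(labels).encode(), digest_size=4).digest()
    return (base * 100003 + int.from_bytes(digest, "big")) % (2**31)


def stratify_samples(labels: pd.DataFrame) -> dict:
    """Partition sample ids by HPV status; unlabeled samples are dropped."""
    out = {s: [] for s in STRATA}
    for sample_id, status in labels[["sample_id", "hpv_status"]].itertuples(
        index=False
    ):
        out[f"hpv_{status}"].append(sample_id)
    for stratum, ids in out.items():
        if not ids:
            logger.warning("stratum %s is empty and will be skipped", stratum)
    return out


def _validate_and_enrich(
    seeds: set,
    data: dict,
    evidence: list,
    params: PipelineParams,
    stratum: str,
    label: str,
) -> dict:
    """Expand seeds through the PPI, validate, and run drug enrichment."""
    universe, _, _ = drugs_mod.build_universe(data["drugs"])
    if seeds:
        nmap = ppi_mod.expand_neighbors(
            seeds, data["ppi"], params.ppi_min_score, params.ppi_strict
        )
    else:
        nmap = ppi_mod.NeighborMap({}, params.ppi_min_score)
    validated_direct = lit_mod.validate_genes(seeds, evidence, params.min_articles)
    validated_neighbors = lit_mod.validate_genes(
        nmap.neighbors, evidence, params.min_articles
    )
    vmap = nmap.restrict(validated_neighbors.genes)
    if validated_direct.genes or vmap.neighbors:
        results = drugs_mod.enrich_all(
            data["drugs"],
            validated_direct.genes,
            vmap,
            alpha=params.alpha,
            n_permutations=params.drug_permutations,
            seed=stage_seed(params.seed, stratum, label, "drugs"),
        )
    else:
        results = pd.DataFrame(
            columns=["drug_id", "drug_name", "K", "n", "x", "p_hypergeom",
                     "p_empirical", "q_hypergeom", "q_empirical", "retained",
                     "targets_direct_risk", "classification",
                     "overlapping_genes", "risk_provenance"]
        )
    return {
        "neighbor_map": nmap,
        "validated_direct": validated_direct,
        "validated_neighbors": validated_neighbors,
        "validated_neighbor_map": vmap,
        "drug_results": results,
        "universe_size": len(universe),
        "risk_in_universe": len(set(seeds) & universe),
        "annotated_genes": len((set(seeds) | nmap.neighbors) & universe),
    }


def run_stratum(
    stratum: str,
    sample_ids: list,
    data: dict,
    evidence: list,
    params: PipelineParams,
) -> StratumResult:
    """Run every stage for one HPV stratum."""
    result = StratumResult(stratum=stratum, n_samples=len(sample_ids))
    sample_set = set(sample_ids)

    cnv = data["cnv"][data["cnv"]["sample_id"].isin(sample_set)]
    for source, direction in CNV_SOURCES.items():
        stats = cnv_mod.analyze_cnv(
            cnv,
            direction,
            n_permutations=params.cnv_permutations,
            seed=stage_seed(params.seed, stratum, source),
            amplitude_gate=params.amplitude_gate,
            score_convention=params.score_convention,
        )
        result.gene_stats[source] = stats
        result.risk_sets[source] = cnv_mod.select_risk_genes(
            stats,
            "gistic_like_score",
            alpha=params.alpha,
            cutoff_method=params.cutoff_method,
            cutoff_param=params.cutoff_param,
            cutoff_scope=params.cutoff_scope,
            stratum=stratum,
            source=source,
        )

    maf = data["maf"][data["maf"]["sample_id"].isin(sample_set)]
    som_stats = som_mod.analyze_som(
        maf,
        data["lengths"],
        cohort_size=len(sample_ids),
        n_simulations=params.som_simulations,
        seed=stage_seed(params.seed, stratum, "somatic_mutation"),
        permutation_method=params.som_permutation_method,
    )
    result.gene_stats["somatic_mutation"] = som_stats
    result.risk_sets["somatic_mutation"] = cnv_mod.select_risk_genes(
        som_stats,
        "mutation_score",
        alpha=params.alpha,
        cutoff_method=params.cutoff_method,
        cutoff_param=params.cutoff_param,
        cutoff_scope=params.cutoff_scope,
        stratum=stratum,
        source="somatic_mutation",
    ) if len(som_stats) else cnv_mod.RiskGeneSet(
        set(), float("nan"), "empty", stratum, "somatic_mutation", params.alpha
    )

    # per-source expansion/validation/enrichment for the summary table
    for source in SOURCES:
        seeds = result.risk_sets[source].genes
        result.per_source[source] = _validate_and_enrich(
            seeds, data, evidence, params, stratum, source
        )

    # union of the three sources -> the stratum's final candidate list
    union_seeds = set().union(*(result.risk_sets[s].genes for s in SOURCES))
    union = _validate_and_enrich(
        union_seeds, data, evidence, params, stratum, "union"
    )
    result.neighbor_map = union["neighbor_map"]
    result.validated_direct = union["validated_direct"]
    result.validated_neighbors = union["validated_neighbors"]
    result.drug_results = union["drug_results"]
    result.sankey_edges = drugs_mod.build_sankey_edges(
        union["drug_results"], union["validated_neighbor_map"]
    ) if len(union["drug_results"]) else pd.DataFrame(
        columns=["drug", "target_gene", "risk_gene"]
    )
    result.metadata = {
        "stratum": stratum,
        "n_samples": len(sample_ids),
        "params": dataclasses.asdict(params),
        "union_risk_genes": sorted(union_seeds),
    }
    return result


def run_full(data: dict, params: PipelineParams | None = None) -> dict:
    """End-to-end run over in-memory inputs.

    ``data`` carries the keys ``cnv`` (long-format table), ``labels``,
    ``maf`` (normalized columns gene / variant_classification / sample_id),
    ``lengths`` (Series), ``ppi``, ``drugs``, ``abstracts`` (list of dicts or
    records) and ``lexicon`` (gene symbols for the literature extractor).
    Returns ``{stratum: StratumResult}`` for every non-empty stratum.
    """
    params = params or PipelineParams()
    maf = data["maf"]
    if "Hugo_Symbol" in maf.columns:  # raw MAF column names
        maf = pd.DataFrame(
            {
                "gene": maf["Hugo_Symbol"],
                "variant_classification": maf["Variant_Classification"],
                "sample_id": som_mod.truncate_to_patient(
                    maf["Tumor_Sample_Barcode"]
                ),
            }
        )
    data = dict(data, maf=maf)

    cleaned, drop_counts = lit_mod.clean_abstracts(
        data["abstracts"], min_year=params.min_year
    )
    logger.info("abstract cleaning dropped %s", dict(drop_counts))
    drug_names = set(data["drugs"]["drug_name"].unique())
    extractor = lit_mod.LexiconExtractor(data["lexicon"], drug_names)
    evidence = lit_mod.extract_targets(cleaned, extractor)

    strata = stratify_samples(data["labels"])
    results = {}
    for stratum, sample_ids in strata.items():
        if not sample_ids:
            continue
        logger.info("running stratum %s (%d samples)", stratum, len(sample_ids))
        results[stratum] = run_stratum(stratum, sample_ids, data, evidence, params)
        results[stratum].metadata["abstract_drop_counts"] = dict(drop_counts)
    return results


def run_from_files(paths: dict, params: PipelineParams | None = None) -> dict:
    """Load every input from disk (see :mod:`redrug.io`) and run the pipeline."""
    data = {
        "cnv": io_mod.read_cnv_long(paths["cnv"]),
        "labels": io_mod.read_labels(paths["labels"]),
        "maf": io_mod.read_maf(paths["maf"]),
        "lengths": io_mod.read_gene_lengths(paths["lengths"]),
        "ppi": io_mod.read_ppi(paths["ppi"], paths.get("ppi_alias")),
        "drugs": io_mod.read_drug_table(paths["drugs"]),
        "abstracts": io_mod.read_abstracts(paths["abstracts"]),
        "lexicon": io_mod.read_lexicon(paths["lexicon"]),
    }
    return run_full(data, params)


_SUMMARY_COLUMNS = [
    "cohort_type",
    "high_risk_genes",
    "risk_genes_drug_targets",
    "immediate_neighbors",
    "drug_annotated_genes",
    "significant_medications",
]


def report_summary(results: dict) -> pd.DataFrame:
    """Six-column per-stratum x per-source summary table.

    Counts per row: risk genes selected, risk genes that are drug targets,
    immediate PPI neighbors, drug-annotated genes (risk + neighbors in the
    druggable universe), and drugs passing the dual significance gate for
    that source's risk set.
    """
    label = {
        "hpv_positive": "HPV-Positive",
        "hpv_negative": "HPV-Negative",
        "cnv_amplification": "CNV Amplification",
        "cnv_deletion": "CNV Deletion",
        "somatic_mutation": "Somatic Mutation",
    }
    rows = []
    for stratum in STRATA:
        res = results.get(stratum)
        for source in SOURCES:
            name = f"{label[stratum]} {label[source]}"
            if res is None:
                rows.append(dict(zip(_SUMMARY_COLUMNS, [name, 0, 0, 0, 0, 0])))
                continue
            stage = res.per_source[source]
            dr = stage["drug_results"]
            rows.append(
                {
                    "cohort_type": name,
                    "high_risk_genes": len(res.risk_sets[source].genes),
                    "risk_genes_drug_targets": stage["risk_in_universe"],
                    "immediate_neighbors": len(stage["neighbor_map"].neighbors),
                    "drug_annotated_genes": stage["annotated_genes"],
                    "significant_medications": int(dr["retained"].sum())
                    if len(dr)
                    else 0,
                }
            )
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


def write_results(results: dict, outdir) -> None:
    """Write every stage output as TSV/JSON under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    import json

    for stratum, res in results.items():
        sdir = outdir / stratum
        sdir.mkdir(exist_ok=True)
        for source, stats in res.gene_stats.items():
            io_mod.write_gene_stats(stats, sdir / f"{source}.stats.tsv")
        for source, rset in res.risk_sets.items():
            io_mod.write_risk_gene_set(
                rset,
                sdir / f"{source}.risk",
                extra_metadata={"seed": res.metadata["params"]["seed"]},
            )
        if res.neighbor_map is not None:
            io_mod.write_neighbor_map(res.neighbor_map, sdir / "neighbors")
        if res.validated_direct is not None:
            with open(sdir / "validated_genes.json", "w") as fh:
                json.dump(
                    {
                        "direct": res.validated_direct.support,
                        "neighbors": res.validated_neighbors.support,
                        "min_articles": res.validated_direct.min_articles,
                    },
                    fh,
                    indent=2,
                )
        if res.drug_results is not None and len(res.drug_results):
            dr = res.drug_results.copy()
            dr["risk_provenance"] = dr["risk_provenance"].map(json.dumps)
            dr.to_csv(sdir / "drug_enrichment.tsv", sep="\t", index=False)
        if res.sankey_edges is not None:
            res.sankey_edges.to_csv(sdir / "sankey_edges.tsv", sep="\t", index=False)
        with open(sdir / "run_metadata.json", "w") as fh:
            json.dump(res.metadata, fh, indent=2, default=str)
    report_summary(results).to_csv(outdir / "summary.tsv", sep="\t", index=False)
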