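"""Readers and writers for the pipeline's tabular input and output formats.

Inputs are plain tab- or comma-delimited text in the shapes the public
resources export them: GDC-style gene-level copy-number tables (one file per
sample plus a sample sheet, or one combined long table), MAF mutation tables,
two-column gene-length TSVs or GENCODE-style GTFs, STRING-links-style PPI
edge lists with an optional protein-id -> symbol alias table, flat drug–gene
interaction CSVs, and JSONL/CSV abstract corpora.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from .somatic import truncate_to_patient

logger = logging.getLogger(__name__)

__all__ = [
    "read_cnv_long",
    "read_gdc_cnv",
    "read_labels",
    "read_maf",
    "read_gene_lengths",
    "cds_lengths_from_gtf",
    "read_ppi",
    "read_drug_table",
    "read_abstracts",
    "read_lexicon",
    "write_gene_stats",
    "write_risk_gene_set",
    "write_neighbor_map",
]

_CNV_COLUMNS = ["sample_id", "gene", "chromosome", "start", "end", "copy_number"]


def read_cnv_long(path) -> pd.DataFrame:
    """Combined long-format copy-number TSV (one row per sample x gene)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_CNV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CNV table missing columns: {sorted(missing)}")
    return df[_CNV_COLUMNS]


def read_gdc_cnv(sample_sheet_path, data_dir) -> pd.DataFrame:
    """GDC layout: one gene-level TSV per sample plus a file -> sample sheet.

    The sample sheet is a TSV with columns ``file_name`` and ``sample_id``;
    each per-sample file carries ``gene_name``, ``chromosome``, ``start``,
    ``end``, ``copy_number`` columns.
    """
    sheet = pd.read_csv(sample_sheet_path, sep="\t")
    data_dir = Path(data_dir)
    frames = []
    for file_name, sample_id in sheet[["file_name", "sample_id"]].itertuples(
        index=False
    ):
        per = pd.read_csv(data_dir / file_name, sep="\t")
        per = per.rename(columns={"gene_name": "gene"})
        per["sample_id"] = sample_id
        frames.append(per[_CNV_COLUMNS])
    if not frames:
        raise ValueError("sample sheet lists no files")
    return pd.concat(frames, ignore_index=True)


def read_labels(path) -> pd.DataFrame:
    """Sample -> HPV status TSV with columns sample_id, hpv_status."""
    df = pd.read_csv(path, sep="\t")
    bad = set(df["hpv_status"].unique()) - {"positive", "negative"}
    if bad:
        raise ValueError(f"hpv_status must be positive/negative, found {sorted(bad)}")
    return df[["sample_id", "hpv_status"]]


def read_maf(path, patient_prefix: int = 12) -> pd.DataFrame:
    """MAF reader: tab-delimited, '#' comments, optionally gzipped.

    Only Hugo_Symbol, Variant_Classification and Tumor_Sample_Barcode are
    required; barcodes are truncated to patient identifiers (default: the
    12-character TCGA patient prefix).
    """
    df = pd.read_csv(path, sep="\t", comment="#", low_memory=False)
    required = ["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"MAF missing required columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "gene": df["Hugo_Symbol"],
            "variant_classification": df["Variant_Classification"],
            "sample_id": truncate_to_patient(
                df["Tumor_Sample_Barcode"], patient_prefix
            ),
        }
    )
    return out


def read_gene_lengths(path) -> pd.Series:
    """Two-column TSV (gene, cds_length) -> Series indexed by gene."""
    df = pd.read_csv(path, sep="\t")
    s = df.set_index("gene")["cds_length"].astype(int)
    if s.index.has_duplicates:
        raise ValueError("gene-length table has duplicate genes")
    if (s <= 0).any():
        raise ValueError("CDS lengths must be positive")
    return s


def cds_lengths_from_gtf(path) -> pd.Series:
    """Per-gene CDS length from a GENCODE-style GTF.

    CDS length is the summed length of the merged, strand-agnostic union of a
    gene's CDS intervals (GTF coordinates are 1-based inclusive).
    """
    import pyranges as pr  # optional extra

    gr = pr.read_gtf(path)
    cds = gr[gr.Feature == "CDS"]
    lengths = {}
    df = cds.df
    for gene, group in df.groupby("gene_name"):
        merged = pr.PyRanges(group[["Chromosome", "Start", "End"]]).merge()
        lengths[gene] = int((merged.End - merged.Start).sum())
    return pd.Series(lengths, name="cds_length").sort_index()


def read_ppi(path, alias_path=None) -> pd.DataFrame:
    """STRING-links-style edge list, optionally mapped to gene symbols.

    The links file is whitespace- or tab-delimited with columns
    (protein1, protein2, combined_score) — or already (gene_a, gene_b,
    combined_score).  ``alias_path`` is a two-column TSV (protein_id, symbol);
    edges with an unmappable endpoint are dropped with a logged count.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "gene_a" not in df.columns:
        df = df.rename(columns={"protein1": "gene_a", "protein2": "gene_b"})
    df = df[["gene_a", "gene_b", "combined_score"]]
    if alias_path is not None:
        alias = pd.read_csv(alias_path, sep="\t")
        mapping = alias.set_index(alias.columns[0])[alias.columns[1]]
        before = len(df)
        df["gene_a"] = df["gene_a"].map(mapping)
        df["gene_b"] = df["gene_b"].map(mapping)
        df = df.dropna(subset=["gene_a", "gene_b"])
        dropped = before - len(df)
        if dropped:
            logger.info("dropped %d PPI edges with unmappable proteins", dropped)
    return df.reset_index(drop=True)


def read_drug_table(path) -> pd.DataFrame:
    """Drug–gene interaction CSV (drug_id, drug_name, gene_symbol, action)."""
    df = pd.read_csv(path)
    if "gene" not in df.columns:
        df = df.rename(columns={"gene_symbol": "gene"})
    required = {"drug_id", "drug_name", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")
    return df


def read_abstracts(path) -> list[dict]:
    """Abstract corpus from JSONL (preferred) or CSV with the same columns."""
    path = Path(path)
    if path.suffix in (".jsonl", ".ndjson"):
        from .literature import read_abstracts_jsonl

        return read_abstracts_jsonl(path)
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    return df[["pmid", "title", "year", "abstract"]].to_dict("records")


def read_lexicon(path) -> set:
    """One-symbol-per-line gene lexicon."""
    return {
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    }


def write_gene_stats(stats: pd.DataFrame, path) -> None:
    stats.rename_axis("gene").reset_index().to_csv(path, sep="\t", index=False)


def write_risk_gene_set(risk_set, path_prefix, extra_metadata=None) -> None:
    """Plain-text gene list plus a JSON sidecar recording the selection."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    genes = sorted(risk_set.genes)
    Path(f"{prefix}.genes.txt").write_text("\n".join(genes) + ("\n" if genes else ""))
    meta = {
        "stratum": risk_set.stratum,
        "source": risk_set.source,
        "n_genes": len(genes),
        "alpha": risk_set.alpha,
        "selection_method": risk_set.selection_method,
        "score_cutoff": risk_set.score_cutoff,
    }
    if extra_metadata:
        meta.update(extra_metadata)
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def write_neighbor_map(neighbor_map, path_prefix) -> None:
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    neighbor_map.to_frame().to_csv(f"{prefix}.tsv", sep="\t", index=False)
    with open(f"{prefix}.json", "w") as fh:
        json.dump(
            {
                "cutoff": neighbor_map.cutoff,
                "entries": {n: sorted(s) for n, s in neighbor_map.entries.items()},
            },
            fh,
            indent=2,
        )
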