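"""Somatic-mutation burden analysis with gene-length normalization.

Non-synonymous mutation counts per gene are tested against a coding-sequence
length-proportional null: under the null, each of the cohort's N total
mutations (synonymous included, to establish an unbiased background rate)
lands in gene j with probability L_j / sum_k L_k, where L_j is the gene's CDS
length.  Two tests are run per gene — the exact binomial tail at p_j, and an
empirical test against a simulated multinomial null — and BH-adjusted.
Dual-significant genes are ranked by MutationScore = (mutations per bp) x
(percent of patients mutated).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .stats import bh_fdr, binomial_tail_p

logger = logging.getLogger(__name__)

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "filter_nonsynonymous",
    "truncate_to_patient",
    "gene_mutation_stats",
    "som_binomial_test",
    "som_multinomial_permutation",
    "mutation_score",
    "analyze_som",
]

#: MAF Variant_Classification values counted as non-synonymous
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)

#: synonymous / non-coding classes silently dropped by the filter
_KNOWN_OTHER = frozenset(
    {
        "Silent",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "Intron",
        "IGR",
        "RNA",
        "Targeted_Region",
        "De_novo_Start_InFrame",
        "De_novo_Start_OutOfFrame",
    }
)

#: standard TCGA barcode prefix length identifying the patient
TCGA_PATIENT_PREFIX = 12


def filter_nonsynonymous(
    records: pd.DataFrame,
    allowlist: frozenset = NONSYNONYMOUS_CLASSES,
) -> tuple[pd.DataFrame, int]:
    """Keep non-synonymous mutations; return them plus the total count N.

    N counts every mutation, synonymous included — it is the binomial trial
    size of the length-based test.  Classification labels outside the known
    MAF vocabulary are dropped with a warning (an explicit ``allowlist``
    overrides which labels are retained).
    """
    if len(records) == 0:
        return records.copy(), 0
    cls = records["variant_classification"]
    unknown = set(cls.unique()) - set(allowlist) - set(_KNOWN_OTHER)
    if unknown:
        warnings.warn(
            f"unknown Variant_Classification labels dropped: {sorted(unknown)}",
            stacklevel=2,
        )
    kept = records[cls.isin(allowlist)].copy()
    return kept, int(len(records))


def truncate_to_patient(
    barcodes: pd.Series, prefix: int = TCGA_PATIENT_PREFIX
) -> pd.Series:
    """Truncate tumor sample barcodes to patient identifiers (TCGA 12-char)."""
    return barcodes.str.slice(0, prefix)


def gene_mutation_stats(
    records: pd.DataFrame,
    cds_lengths: pd.Series,
    cohort_size: int,
) -> pd.DataFrame:
    """Per-gene non-synonymous counts, unique patients, and normalized burden.

    Parameters
    ----------
    records : non-synonymous mutation table with columns ``gene`` and
        ``sample_id`` (already truncated to patient identifiers).
    cds_lengths : Series mapping gene symbol -> CDS length in bp (the
        annotation universe).  Mutated genes absent from it are excluded from
        testing with a logged warning.
    cohort_size : number of patients in the stratum.

    Returns a DataFrame indexed by gene with ``mutation_count``,
    ``patient_count``, ``cds_length``, ``normalized_count`` (mutations / bp)
    and ``frequency_pct`` (percent of cohort patients mutated).  Only mutated
    genes get a row.
    """
    if cohort_size < 1:
        raise ValueError("cohort_size must be >= 1")
    known = records["gene"].isin(cds_lengths.index)
    skipped = sorted(records.loc[~known, "gene"].unique())
    if skipped:
        logger.warning(
            "%d mutated genes absent from the annotation were excluded: %s",
            len(skipped),
            skipped[:10],
        )
    rec = records[known]
    agg = rec.groupby("gene", sort=True).agg(
        mutation_count=("sample_id", "size"),
        patient_count=("sample_id", "nunique"),
    )
    agg["cds_length"] = cds_lengths.reindex(agg.index).astype(int)
    agg["normalized_count"] = agg["mutation_count"] / agg["cds_length"]
    agg["frequency_pct"] = 100.0 * agg["patient_count"] / cohort_size
    agg.attrs["cohort_size"] = cohort_size
    agg.attrs["skipped_genes"] = skipped
    return agg


def _length_probabilities(cds_lengths: pd.Series) -> pd.Series:
    lengths = cds_lengths.astype(float)
    if (lengths <= 0).any():
        raise ValueError("CDS lengths must be positive")
    return lengths / lengths.sum()


def som_binomial_test(
    stats: pd.DataFrame, n_total: int, cds_lengths: pd.Series
) -> np.ndarray:
    """Binomial tail P(X >= x) with per-gene p = L_gene / sum of all CDS lengths.

    ``n_total`` is the cohort's total mutation count including synonymous
    events; the denominator of p runs over the full annotation universe.
    """
    probs = _length_probabilities(cds_lengths)
    return np.array(
        [
            binomial_tail_p(int(x), int(n_total), float(probs[g]))
            for g, x in zip(stats.index, stats["mutation_count"])
        ]
    )


def som_multinomial_permutation(
    stats: pd.DataFrame,
    cds_lengths: pd.Series,
    n_total: int,
    n_simulations: int = 10000,
    seed: int = 0,
    method: str = "multinomial",
    chunk_size: int = 1000,
) -> np.ndarray:
    """Empirical p-values against a length-proportional multinomial null.

    Each simulation scatters ``n_total`` mutations over the full annotation
    universe with probabilities proportional to CDS length (conserving the
    total), and the per-gene simulated counts form the null.  With
    ``method="binomial"`` the per-gene marginals Binomial(n_total, p_j) are
    drawn instead — distributionally identical per gene and cheaper for large
    universes, but without the draw-level conservation constraint.
    """
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    if method not in ("multinomial", "binomial"):
        raise ValueError(f"unknown method {method!r}")
    probs = _length_probabilities(cds_lengths)
    tested = stats.index
    positions = probs.index.get_indexer(tested)
    if (positions < 0).any():
        raise ValueError("tested genes must be present in the annotation universe")
    x_obs = stats["mutation_count"].to_numpy()
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(tested), dtype=np.int64)
    p_vec = probs.to_numpy()
    if method == "multinomial":
        done = 0
        while done < n_simulations:
            block = min(chunk_size, n_simulations - done)
            draws = rng.multinomial(n_total, p_vec, size=block)
            exceed += (draws[:, positions] >= x_obs[None, :]).sum(axis=0)
            done += block
    else:
        for j, pos in enumerate(positions):
            counts = rng.binomial(n_total, p_vec[pos], size=n_simulations)
            exceed[j] = int((counts >= x_obs[j]).sum())
    return (1 + exceed) / (n_simulations + 1)


def mutation_score(stats: pd.DataFrame) -> np.ndarray:
    """MutationScore = normalized count (mutations/bp) x percent patient frequency.

    Balances per-gene mutation amplitude with cohort prevalence; units are
    (mutations per bp) x percent.
    """
    return (stats["normalized_count"] * stats["frequency_pct"]).to_numpy()


def analyze_som(
    maf: pd.DataFrame,
    cds_lengths: pd.Series,
    cohort_size: int | None = None,
    n_simulations: int = 10000,
    seed: int = 0,
    permutation_method: str = "multinomial",
) -> pd.DataFrame:
    """Full per-gene mutation statistics for one stratum.

    ``maf`` must carry ``gene``, ``variant_classification`` and ``sample_id``
    columns (patient-level identifiers).  ``cohort_size`` defaults to the
    number of distinct patients in the table.
    """
    if cohort_size is None:
        cohort_size = int(maf["sample_id"].nunique())
    nonsyn, n_total = filter_nonsynonymous(maf)
    stats = gene_mutation_stats(nonsyn, cds_lengths, cohort_size)
    if len(stats) == 0:
        return stats
    stats["p_binomial"] = som_binomial_test(stats, n_total, cds_lengths)
    stats["p_empirical"] = som_multinomial_permutation(
        stats, cds_lengths, n_total, n_simulations, seed, permutation_method
    )
    stats["q_binomial"] = bh_fdr(stats["p_binomial"])
    stats["q_empirical"] = bh_fdr(stats["p_empirical"])
    stats["mutation_score"] = mutation_score(stats)
    stats.attrs["n_total_mutations"] = n_total
    stats.attrs["cohort_size"] = cohort_size
    stats.attrs["n_simulations"] = n_simulations
    stats.attrs["seed"] = seed
    return stats
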