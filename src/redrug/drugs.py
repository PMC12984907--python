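"""Drug–target enrichment against validated risk-gene sets.

Every drug's target set is tested for overlap with the risk set (validated
direct risk genes plus validated PPI neighbors, intersected with the
druggable-gene universe) two ways:

* a right-tailed hypergeometric test — given M druggable genes of which K are
  the drug's targets and n are risk genes, the probability of an overlap at
  least as large as observed;
* an empirical permutation test — random gene sets of size n drawn uniformly
  without replacement from the universe, overlap recorded per permutation,
  add-one empirical p.  One sampled set per permutation is shared across all
  drugs, which both matches the resampling scheme and keeps the cost linear
  in the number of permutations.

Both p-vectors are BH-adjusted across drugs; candidates must clear q < alpha
in both.  Retained drugs are classified "direct" (target >= 1 validated risk
gene), "indirect" (target >= 1 validated neighbor) or "both".
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .ppi import NeighborMap
from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "build_universe",
    "drug_hypergeom_test",
    "drug_permutation_test",
    "enrich_all",
    "build_sankey_edges",
]


def build_universe(interactions: pd.DataFrame):
    """Druggable-gene universe and per-drug target sets from an interaction table.

    ``interactions`` needs columns ``drug_id``, ``drug_name``, ``gene``.
    Duplicate (drug, gene) rows count once.  Returns
    ``(universe, targets, names)`` where ``targets`` maps drug_id ->
    frozenset of target genes and ``names`` maps drug_id -> drug_name.
    """
    if len(interactions) == 0:
        raise ValueError("interaction table must be non-empty")
    universe = frozenset(interactions["gene"])
    targets = {
        drug: frozenset(group["gene"])
        for drug, group in interactions.groupby("drug_id", sort=True)
    }
    names = (
        interactions.drop_duplicates("drug_id")
        .set_index("drug_id")["drug_name"]
        .to_dict()
    )
    return universe, targets, names


def drug_hypergeom_test(drug_targets, risk_set, universe) -> float:
    """Right-tailed hypergeometric P(X >= x) for the observed target overlap."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    targets = set(drug_targets) & universe
    risk = set(risk_set) & universe
    M, K, n = len(universe), len(targets), len(risk)
    x = len(targets & risk)
    if x <= 0:
        return 1.0
    return float(_sps.hypergeom.sf(x - 1, M, K, n))


def _sample_overlap_counts(
    target_matrix: np.ndarray,
    M: int,
    n: int,
    n_permutations: int,
    rng: np.random.Generator,
    chunk_size: int | None = None,
) -> np.ndarray:
    """Overlap counts of random n-subsets of the universe with each drug.

    ``target_matrix`` is (M, D) boolean.  Returns an (n_permutations, D)
    integer matrix; permutation i uses one sampled gene set for every drug.
    """
    D = target_matrix.shape[1]
    if chunk_size is None:
        chunk_size = max(1, int(2e6) // max(M, 1))
    counts = np.empty((n_permutations, D), dtype=np.int32)
    tm = target_matrix.astype(np.float32)
    done = 0
    while done < n_permutations:
        block = min(chunk_size, n_permutations - done)
        # uniform n-subset per row: the n smallest of M iid uniforms
        r = rng.random((block, M))
        idx = np.argpartition(r, n - 1, axis=1)[:, :n] if n < M else np.tile(
            np.arange(M), (block, 1)
        )
        member = np.zeros((block, M), dtype=np.float32)
        np.put_along_axis(member, idx, 1.0, axis=1)
        counts[done : done + block] = np.rint(member @ tm).astype(np.int32)
        done += block
    return counts


def drug_permutation_test(
    drug_targets,
    risk_set,
    universe,
    n_permutations: int = 100000,
    seed: int = 0,
) -> float:
    """Empirical p for one drug from uniform risk-set resampling."""
    universe_arr = np.array(sorted(set(universe)))
    M = universe_arr.size
    risk = set(risk_set) & set(universe_arr)
    n = len(risk)
    if n > M:
        raise ValueError("risk-set size exceeds the universe")
    targets = set(drug_targets) & set(universe_arr)
    x_obs = len(targets & risk)
    tmat = np.isin(universe_arr, sorted(targets))[:, None]
    rng = np.random.default_rng(seed)
    counts = _sample_overlap_counts(tmat, M, n, n_permutations, rng)[:, 0]
    return float((1 + int((counts >= x_obs).sum())) / (n_permutations + 1))


def enrich_all(
    interactions: pd.DataFrame,
    direct_genes,
    neighbor_map: NeighborMap | None = None,
    alpha: float = 0.05,
    n_permutations: int = 100000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dual enrichment test and classification over every drug in the table.

    Parameters
    ----------
    interactions : drug–gene interaction table (``drug_id``, ``drug_name``,
        ``gene``).
    direct_genes : validated direct risk genes.
    neighbor_map : validated PPI neighbors with their seed provenance (may be
        None / empty).
    alpha : FDR level for the dual gate.

    Returns one row per drug with K, n, x, both p-values, both q-values, a
    ``retained`` flag (q < alpha in both tests), the classification of
    retained drugs, the overlapping genes and their provenance.  Drugs with
    zero overlap are scored (p = 1) and kept in the table for audit but can
    never be retained.
    """
    universe, targets, names = build_universe(interactions)
    direct = set(direct_genes) & universe
    neighbor_map = neighbor_map or NeighborMap({})
    neighbors = neighbor_map.neighbors & universe
    risk = direct | neighbors
    M, n = len(universe), len(risk)
    drug_ids = sorted(targets)

    if n == 0:
        warnings.warn("risk set is empty after intersecting with the universe",
                      stacklevel=2)
        return pd.DataFrame(
            columns=[
                "drug_id", "drug_name", "K", "n", "x", "p_hypergeom",
                "p_empirical", "q_hypergeom", "q_empirical", "retained",
                "classification", "overlapping_genes", "risk_provenance",
            ]
        )

    universe_arr = np.array(sorted(universe))
    tmat = np.zeros((M, len(drug_ids)), dtype=bool)
    gene_pos = {g: i for i, g in enumerate(universe_arr)}
    for j, drug in enumerate(drug_ids):
        for g in targets[drug]:
            tmat[gene_pos[g], j] = True
    risk_mask = np.array([g in risk for g in universe_arr])
    x_obs = (tmat & risk_mask[:, None]).sum(axis=0)

    p_hyper = np.array(
        [
            float(_sps.hypergeom.sf(x - 1, M, K, n)) if x > 0 else 1.0
            for x, K in zip(x_obs, tmat.sum(axis=0))
        ]
    )
    rng = np.random.default_rng(seed)
    counts = _sample_overlap_counts(tmat, M, n, n_permutations, rng)
    p_emp = (1 + (counts >= x_obs[None, :]).sum(axis=0)) / (n_permutations + 1)

    q_hyper = bh_fdr(p_hyper)
    q_emp = bh_fdr(p_emp)

    rows = []
    for j, drug in enumerate(drug_ids):
        overlap = set(targets[drug]) & risk
        retained = bool(q_hyper[j] < alpha and q_emp[j] < alpha)
        hits_direct = bool(overlap & direct)
        hits_neighbor = bool(overlap & neighbors)
        if retained and hits_direct and hits_neighbor:
            classification = "both"
        elif retained and hits_direct:
            classification = "direct"
        elif retained and hits_neighbor:
            classification = "indirect"
        else:
            classification = ""
        provenance = {}
        for g in sorted(overlap):
            if g in direct:
                provenance[g] = "direct"
            else:
                provenance[g] = "neighbor of " + ",".join(
                    sorted(neighbor_map.seeds_of(g))
                )
        rows.append(
            {
                "drug_id": drug,
                "drug_name": names[drug],
                "K": int(tmat[:, j].sum()),
                "n": n,
                "x": int(x_obs[j]),
                "p_hypergeom": p_hyper[j],
                "p_empirical": float(p_emp[j]),
                "q_hypergeom": q_hyper[j],
                "q_empirical": float(q_emp[j]),
                "retained": retained,
                "targets_direct_risk": hits_direct,
                "classification": classification,
                "overlapping_genes": ";".join(sorted(overlap)),
                "risk_provenance": provenance,
            }
        )
    out = pd.DataFrame(rows)
    out = out.sort_values(
        ["q_hypergeom", "p_hypergeom", "q_empirical", "drug_id"]
    ).reset_index(drop=True)
    out.attrs.update({"M": M, "n": n, "alpha": alpha,
                      "n_permutations": n_permutations, "seed": seed})
    return out


def build_sankey_edges(
    results: pd.DataFrame,
    neighbor_map: NeighborMap | None = None,
    retained_only: bool = True,
) -> pd.DataFrame:
    """Drug -> target gene -> seed risk gene edge table (Sankey structure).

    Direct risk-gene targets map to themselves as the risk gene; neighbor
    targets map to each seed risk gene they are adjacent to.
    """
    neighbor_map = neighbor_map or NeighborMap({})
    rows = []
    subset = results[results["retained"]] if retained_only else results
    for rec in subset.itertuples(index=False):
        genes = [g for g in rec.overlapping_genes.split(";") if g]
        for g in genes:
            prov = rec.risk_provenance.get(g, "")
            if prov == "direct":
                rows.append({"drug": rec.drug_name, "target_gene": g, "risk_gene": g})
            else:
                for seed in sorted(neighbor_map.seeds_of(g)):
                    rows.append(
                        {"drug": rec.drug_name, "target_gene": g, "risk_gene": seed}
                    )
    return pd.DataFrame(rows, columns=["drug", "target_gene", "risk_gene"])
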