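"""Protein–protein interaction neighbor expansion.

Risk genes are expanded to their immediate network neighbors through edges at
or above a combined-score confidence cutoff (STRING convention: scores are
integers 0–1000, with 700 the customary high-confidence band).  The expansion
keeps neighbor -> {seed risk genes} provenance, which downstream drug
classification and the Sankey report rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["NeighborMap", "expand_neighbors"]

DEFAULT_MIN_SCORE = 700


@dataclass
class NeighborMap:
    """Mapping neighbor gene -> set of seed risk genes it is adjacent to.

    No neighbor is itself a seed; every (neighbor, seed) pair is backed by an
    edge meeting the score cutoff.
    """

    entries: dict = field(default_factory=dict)
    cutoff: int = DEFAULT_MIN_SCORE

    @property
    def neighbors(self) -> set:
        return set(self.entries)

    def seeds_of(self, neighbor: str) -> set:
        return self.entries.get(neighbor, set())

    def restrict(self, keep) -> "NeighborMap":
        """Sub-map containing only the given neighbors (e.g. validated ones)."""
        keep = set(keep)
        return NeighborMap(
            {g: set(s) for g, s in self.entries.items() if g in keep}, self.cutoff
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"neighbor": n, "seed": s}
            for n, seeds in sorted(self.entries.items())
            for s in sorted(seeds)
        ]
        return pd.DataFrame(rows, columns=["neighbor", "seed"])


def expand_neighbors(
    seeds,
    edges: pd.DataFrame,
    min_score: int = DEFAULT_MIN_SCORE,
    strict: bool = False,
    max_neighbors: int | None = None,
) -> NeighborMap:
    """Immediate neighbors of the seed genes above the confidence cutoff.

    Parameters
    ----------
    seeds : iterable of gene symbols (must be non-empty).
    edges : DataFrame with columns ``gene_a``, ``gene_b``, ``combined_score``
        (undirected; duplicated reversed rows are harmless).
    min_score : combined-score cutoff; edges at the cutoff are kept unless
        ``strict`` is True (then only scores strictly above pass).
    max_neighbors : optional per-seed cap, keeping the top-scoring neighbors
        of each seed; default unlimited.

    Seeds adjacent to other seeds never appear as neighbors.  Seeds absent
    from the network contribute nothing (logged, not an error).
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seeds must be non-empty")
    scores = edges["combined_score"].to_numpy()
    if np.any((scores < 0) | (scores > 1000)):
        raise ValueError("combined scores must lie in [0, 1000]")
    passing = edges[scores > min_score] if strict else edges[scores >= min_score]

    in_network = set(passing["gene_a"]) | set(passing["gene_b"])
    absent = seeds - (set(edges["gene_a"]) | set(edges["gene_b"]))
    if absent:
        logger.info("%d seed genes absent from the network", len(absent))

    per_seed: dict = {s: [] for s in seeds}
    for a, b, sc in passing[["gene_a", "gene_b", "combined_score"]].itertuples(
        index=False
    ):
        if a == b:
            continue
        if a in seeds and b not in seeds:
            per_seed[a].append((b, sc))
        if b in seeds and a not in seeds:
            per_seed[b].append((a, sc))

    entries: dict = {}
    for seed, pairs in per_seed.items():
        if max_neighbors is not None and len(pairs) > max_neighbors:
            best: dict = {}
            for n, sc in pairs:
                best[n] = max(best.get(n, 0), sc)
            pairs = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:max_neighbors]
        for neighbor, _ in pairs:
            entries.setdefault(neighbor, set()).add(seed)
    return NeighborMap(entries, min_score)
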