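"""Shared statistical primitives used by every pipeline stage.

Three primitives recur throughout the analysis: an exact binomial upper-tail
probability (used for copy-number event counts against a genome-wide
background rate and for mutation counts against a CDS-length-proportional
rate), an add-one-smoothed empirical p-value against a permutation null, and
Benjamini–Hochberg FDR adjustment. All downstream significance gating is a
combination of these three.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = ["PermutationNull", "binomial_tail_p", "empirical_p", "bh_fdr"]


@dataclass(frozen=True)
class PermutationNull:
    """A permutation null distribution of non-negative event counts.

    ``counts[i]`` is the statistic observed in permutation ``i``; ``seed``
    records the RNG seed used to build it (the determinism contract: the same
    seed and inputs reproduce the same null bit-for-bit).
    """

    counts: np.ndarray
    seed: int | None = None
    _sorted: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.size == 0:
            raise ValueError("permutation null must be non-empty")
        if np.any(counts < 0):
            raise ValueError("permutation counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "_sorted", np.sort(counts))

    @property
    def n_permutations(self) -> int:
        return int(self.counts.size)

    def exceedances(self, observed) -> np.ndarray:
        """Number of permutation counts >= each observed value (ties count)."""
        observed = np.asarray(observed)
        return self.n_permutations - np.searchsorted(
            self._sorted, observed, side="left"
        )


def binomial_tail_p(x: int, n: int, p: float) -> float:
    """Exact upper-tail binomial probability P(X >= x), X ~ Binomial(n, p).

    Computed via the survival function rather than naive summation so it is
    stable for large ``n``.  ``x > n`` is allowed and gives 0 (impossible
    event); ``x <= 0`` gives 1.
    """
    if x < 0:
        raise ValueError(f"x must be non-negative, got {x}")
    if n < 1:
        raise ValueError(f"n must be positive, got {n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if x <= 0:
        return 1.0
    if x > n:
        return 0.0
    return float(_sps.binom.sf(x - 1, n, p))


def empirical_p(observed: float, null: PermutationNull | np.ndarray) -> float:
    """Add-one-smoothed empirical p-value against a permutation null.

    Returns ``(1 + #{i : counts[i] >= observed}) / (N + 1)`` where N is the
    number of permutations.  Ties count as exceedances; the +1 smoothing keeps
    the result in ``[1/(N+1), 1]`` so a p-value of exactly zero is impossible.
    """
    if not isinstance(null, PermutationNull):
        null = PermutationNull(np.asarray(null))
    exceed = int(null.exceedances(observed))
    return (1 + exceed) / (null.n_permutations + 1)


def bh_fdr(pvalues, labels=None):
    """Benjamini–Hochberg step-up adjusted q-values, in the input order.

    Parameters
    ----------
    pvalues : array-like of probabilities in [0, 1]
    labels : optional sequence of identifiers; if given, must be unique and
        the same length as ``pvalues`` (returned values stay aligned to it).

    Returns
    -------
    numpy.ndarray of q-values, capped at 1, with ``q_i >= p_i`` everywhere.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("p-value vector must be non-empty")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if labels is not None:
        labels = list(labels)
        if len(labels) != p.size:
            raise ValueError("labels and p-values must have equal length")
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
    return multipletests(p, method="fdr_bh")[1]
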