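"""Gene-level copy-number alteration analysis.

Per analysis stratum (HPV-positive or HPV-negative) and direction
(amplification or deletion), each gene's high-level event count is tested two
ways against the cohort's own genomic instability:

* a binomial test against the genome-wide background rate (the fraction of
  all copy-number observations in the stratum beyond the high-level
  threshold), and
* an empirical permutation test resampling ``n_samples`` values with
  replacement from the pooled copy-number observations.

Both p-vectors are BH-adjusted.  Dual-significant genes are further ranked by
a GISTIC-like composite score (mean log2-adjusted alteration amplitude times
percent frequency of high-level events) and thresholded by a
distribution-based cutoff.

High-level thresholds follow the integer copy-number convention: diploid
baseline is CNV = 2, high-level amplification is CNV > 4, high-level deletion
is CNV = 0 (equivalently CNV < 1 for integers, which is why integer copy
numbers are required at ingest).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import PermutationNull, bh_fdr, binomial_tail_p

logger = logging.getLogger(__name__)

__all__ = [
    "AMP_HIGH_THRESHOLD",
    "DEL_HIGH_THRESHOLD",
    "CNV_CAP",
    "RiskGeneSet",
    "call_cnv_events",
    "background_rate",
    "cnv_binomial_test",
    "cnv_permutation_test",
    "gistic_like_score",
    "select_risk_genes",
    "analyze_cnv",
]

#: high-level amplification: copy number strictly greater than this
AMP_HIGH_THRESHOLD = 4
#: high-level deletion: copy number strictly less than this (== 0 for ints)
DEL_HIGH_THRESHOLD = 1
#: amplification amplitudes are computed on min(CNV, CNV_CAP) so single
#: extreme outliers do not drown out frequent moderate amplifications
CNV_CAP = 7
DIPLOID = 2

_DIRECTIONS = ("amplification", "deletion")


@dataclass
class RiskGeneSet:
    """Genes passing the dual significance gate and the score cutoff."""

    genes: set
    score_cutoff: float
    selection_method: str
    stratum: str = ""
    source: str = ""
    alpha: float = 0.05

    def __len__(self) -> int:
        return len(self.genes)


def _check_direction(direction: str) -> None:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")


def _as_int_array(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError("copy-number input must be non-empty")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError(
            "copy numbers must be integers (high-level deletion CNV = 0 and "
            "CNV < 1 only coincide for integer values)"
        )
    arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError("copy numbers must be non-negative")
    return arr


def _amp_amplitude(cn: np.ndarray, convention: str) -> np.ndarray:
    capped = np.minimum(cn, CNV_CAP)
    if convention == "log2_minus_1":
        # log2(CNV) - 1: zero at the diploid baseline, finite at CNV = 1
        with np.errstate(divide="ignore"):
            return np.log2(capped.astype(float)) - 1.0
    if convention == "log2_of_minus_1":
        with np.errstate(divide="ignore"):
            return np.log2(capped.astype(float) - 1.0)
    raise ValueError(f"unknown score convention {convention!r}")


def call_cnv_events(
    records: pd.DataFrame,
    direction: str,
    amplitude_gate: str = "altered",
    score_convention: str = "log2_minus_1",
) -> pd.DataFrame:
    """Accumulate per-gene high-level event counts and alteration amplitudes.

    Parameters
    ----------
    records : long-format table with columns ``sample_id``, ``gene``,
        ``copy_number`` (one row per gene x sample).
    direction : ``"amplification"`` or ``"deletion"``.
    amplitude_gate : which samples contribute amplitude — ``"altered"``
        (any CNV > 2 for amplification / CNV < 2 for deletion, the default)
        or ``"high"`` (only high-level events).
    score_convention : ``"log2_minus_1"`` (log2(CNV) − 1, default) or
        ``"log2_of_minus_1"`` (log2(CNV − 1)); both zero at diploid.

    Returns
    -------
    DataFrame indexed by gene with columns ``n_samples``,
    ``high_event_count``, ``altered_sample_count``, ``amplitude_sum``,
    ``event_frequency_pct`` (and ``significant_del_count`` for deletions,
    identical to ``high_event_count`` for integer copy numbers).
    """
    _check_direction(direction)
    if amplitude_gate not in ("altered", "high"):
        raise ValueError(f"amplitude_gate must be 'altered' or 'high', got {amplitude_gate!r}")
    if len(records) == 0:
        raise ValueError("records must be non-empty")

    cn = _as_int_array(records["copy_number"].to_numpy())
    gene = records["gene"].to_numpy()

    if direction == "amplification":
        high = cn > AMP_HIGH_THRESHOLD
        altered = cn > DIPLOID
        amplitude = _amp_amplitude(cn, score_convention)
    else:
        high = cn < DEL_HIGH_THRESHOLD
        altered = cn < DIPLOID
        # +1 for minimal deletions (CNV = 1), +2 for significant (CNV = 0)
        amplitude = np.where(cn == 0, 2.0, np.where(cn == 1, 1.0, 0.0))

    gate = high if amplitude_gate == "high" else altered
    contrib = np.where(gate, amplitude, 0.0)

    df = pd.DataFrame(
        {
            "gene": gene,
            "high": high.astype(np.int64),
            "altered": gate.astype(np.int64),
            "amplitude": contrib,
        }
    )
    agg = df.groupby("gene", sort=True).agg(
        n_samples=("high", "size"),
        high_event_count=("high", "sum"),
        altered_sample_count=("altered", "sum"),
        amplitude_sum=("amplitude", "sum"),
    )
    agg["event_frequency_pct"] = 100.0 * agg["high_event_count"] / agg["n_samples"]
    if direction == "deletion":
        agg["significant_del_count"] = agg["high_event_count"]
    agg.attrs["direction"] = direction
    return agg


def background_rate(records, direction: str) -> float:
    """Fraction of all copy-number observations beyond the high-level threshold.

    ``records`` may be the long-format table or a bare array of pooled copy
    numbers; the rate pools every (gene x sample) observation in the stratum.
    """
    _check_direction(direction)
    if isinstance(records, pd.DataFrame):
        values = records["copy_number"].to_numpy()
    else:
        values = records
    cn = _as_int_array(values)
    if direction == "amplification":
        return float(np.mean(cn > AMP_HIGH_THRESHOLD))
    return float(np.mean(cn < DEL_HIGH_THRESHOLD))


def cnv_binomial_test(stats: pd.DataFrame, p_null: float) -> np.ndarray:
    """Per-gene binomial upper-tail p-values against the background rate."""
    return np.array(
        [
            binomial_tail_p(int(x), int(n), p_null)
            for x, n in zip(stats["high_event_count"], stats["n_samples"])
        ]
    )


def cnv_permutation_test(
    stats: pd.DataFrame,
    pooled_values,
    n_samples: int,
    direction: str,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, PermutationNull]:
    """Empirical p-values from resampling the pooled copy-number observations.

    One null distribution is built per stratum x direction (it does not depend
    on the gene) and reused for every gene: each permutation draws
    ``n_samples`` values with replacement from the pooled observations and
    records how many exceed the high-level threshold.
    """
    _check_direction(direction)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    pooled = _as_int_array(pooled_values)
    rng = np.random.default_rng(seed)
    draws = rng.choice(pooled, size=(n_permutations, n_samples), replace=True)
    if direction == "amplification":
        counts = (draws > AMP_HIGH_THRESHOLD).sum(axis=1)
    else:
        counts = (draws < DEL_HIGH_THRESHOLD).sum(axis=1)
    null = PermutationNull(counts, seed=seed)
    exceed = null.exceedances(stats["high_event_count"].to_numpy())
    pvals = (1 + exceed) / (n_permutations + 1)
    return pvals.astype(float), null


def gistic_like_score(stats: pd.DataFrame, direction: str | None = None) -> np.ndarray:
    """Composite amplitude x frequency score, zero when no altered samples.

    Amplification: (amplitude_sum / altered_sample_count) x percent frequency
    of high-level events.  Deletion: (deletion intensity sum / deleted sample
    count) x percent frequency of significant deletions (CNV = 0).
    """
    if direction is None:
        direction = stats.attrs.get("direction")
    _check_direction(direction)
    altered = stats["altered_sample_count"].to_numpy(dtype=float)
    amp_sum = stats["amplitude_sum"].to_numpy(dtype=float)
    if direction == "amplification":
        freq = stats["event_frequency_pct"].to_numpy(dtype=float)
    else:
        sig = stats.get("significant_del_count", stats["high_event_count"])
        freq = 100.0 * sig.to_numpy(dtype=float) / stats["n_samples"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(altered > 0, (amp_sum / np.maximum(altered, 1)) * freq, 0.0)
    return score


def _knee_cutoff(scores: np.ndarray) -> float:
    """Cutoff at the maximum-perpendicular-distance knee of the sorted curve.

    The knee index is where the descending score curve is farthest from the
    chord joining its endpoints; the cutoff is placed halfway between the
    knee point and the score just above it, so the upper tail (before the
    knee) is retained and the bulk (from the knee on) is not.
    """
    s = np.sort(scores)[::-1]
    m = s.size
    if m < 3 or s[0] == s[-1]:
        return float(s[-1])
    x = np.arange(m, dtype=float)
    # chord from (0, s[0]) to (m-1, s[-1])
    dx, dy = m - 1.0, s[-1] - s[0]
    dist = np.abs(dy * x - dx * (s - s[0])) / np.hypot(dx, dy)
    k = int(np.argmax(dist))
    if k == 0:
        return float(s[0])
    return float((s[k - 1] + s[k]) / 2.0)


def select_risk_genes(
    stats: pd.DataFrame,
    score_col: str = "gistic_like_score",
    alpha: float = 0.05,
    cutoff_method: str = "percentile",
    cutoff_param: float = 95.0,
    cutoff_scope: str = "all",
    stratum: str = "",
    source: str = "",
) -> RiskGeneSet:
    """Dual-significance gate plus distribution-based score cutoff.

    A gene is retained iff ``q_binomial < alpha`` AND ``q_empirical < alpha``
    AND its composite score is at or above the cutoff.  The cutoff is either
    the ``cutoff_param``-th percentile of scores (``percentile`` method) or
    the maximum-distance-from-chord knee of the sorted score curve (``knee``);
    ``cutoff_scope`` controls whether the score distribution used is that of
    all genes in the stratum/direction (``"all"``, default) or only the
    dual-significant genes (``"significant"``).
    """
    if cutoff_method not in ("percentile", "knee"):
        raise ValueError(f"unknown cutoff_method {cutoff_method!r}")
    if cutoff_scope not in ("all", "significant"):
        raise ValueError(f"unknown cutoff_scope {cutoff_scope!r}")

    dual = stats[(stats["q_binomial"] < alpha) & (stats["q_empirical"] < alpha)]
    method = f"{cutoff_method}:{cutoff_param}/{cutoff_scope}"
    if len(dual) == 0:
        warnings.warn(
            f"no dual-significant genes at alpha={alpha} ({stratum} {source})",
            stacklevel=2,
        )
        return RiskGeneSet(set(), float("nan"), method, stratum, source, alpha)

    pool = stats if cutoff_scope == "all" else dual
    scores = pool[score_col].to_numpy(dtype=float)
    if cutoff_method == "percentile":
        cutoff = float(np.percentile(scores, cutoff_param))
    else:
        cutoff = _knee_cutoff(scores)
    genes = set(dual.index[dual[score_col] >= cutoff])
    return RiskGeneSet(genes, cutoff, method, stratum, source, alpha)


def analyze_cnv(
    records: pd.DataFrame,
    direction: str,
    n_permutations: int = 1000,
    seed: int = 0,
    amplitude_gate: str = "altered",
    score_convention: str = "log2_minus_1",
) -> pd.DataFrame:
    """Full per-gene statistics table for one stratum and direction.

    Returns a DataFrame indexed by gene with event accumulators, both
    p-values, both BH q-values and the GISTIC-like score.
    """
    stats = call_cnv_events(records, direction, amplitude_gate, score_convention)
    pooled = records["copy_number"].to_numpy()
    p_null = background_rate(pooled, direction)
    n_samples = int(stats["n_samples"].iloc[0])
    stats["p_binomial"] = cnv_binomial_test(stats, p_null)
    stats["p_empirical"], _ = cnv_permutation_test(
        stats, pooled, n_samples, direction, n_permutations, seed
    )
    stats["q_binomial"] = bh_fdr(stats["p_binomial"])
    stats["q_empirical"] = bh_fdr(stats["p_empirical"])
    stats["gistic_like_score"] = gistic_like_score(stats, direction)
    stats["direction"] = direction
    stats.attrs["direction"] = direction
    stats.attrs["background_rate"] = p_null
    stats.attrs["n_permutations"] = n_permutations
    stats.attrs["seed"] = seed
    return stats
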