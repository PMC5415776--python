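"""Merit scoring and Wilcoxon filtering of candidate biomarker sites.

A site's merit is the absolute difference between the two class medians
minus the sum of the within-class sample standard deviations.  Candidate
sites must have positive merit and pass a paired Wilcoxon signed-rank
test (exact null distribution for small n) at ``p < 0.001``.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    BetaMatrix,
    DegenerateInputError,
    SampleSheet,
    pair_samples,
)

logger = logging.getLogger(__name__)

#: Largest effective n for which the exact signed-rank null is enumerated.
EXACT_MAX_N = 25


def merit_score(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """``|median(A) - median(B)| - (sd(A) + sd(B))``, SD with n-1 denominator."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError(
            f"need >= 2 values per class, got {a.size} and {b.size}"
        )
    return float(
        abs(np.median(a) - np.median(b)) - (np.std(a, ddof=1) + np.std(b, ddof=1))
    )


@lru_cache(maxsize=4096)
def _signed_rank_counts(scaled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of sign assignments per value of ``2 * W+``.

    Ranks are midranks doubled to integers so tied ranks stay exact; the
    distribution is built by dynamic-programming convolution over the
    2^n sign vectors.
    """
    total = int(sum(scaled_ranks))
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts


def _exact_two_sided_p(ranks: np.ndarray, w_pos: float) -> float:
    scaled = tuple(sorted(int(round(2.0 * r)) for r in ranks))
    counts = _signed_rank_counts(scaled)
    total = 2.0 ** len(scaled)
    w2 = int(round(2.0 * w_pos))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(paired_diffs: Sequence[float], exact_max_n: int = EXACT_MAX_N) -> float:
    """Two-sided Wilcoxon signed-rank p value for paired differences.

    Zero differences are dropped (classic treatment); if all are zero
    the test is uninformative and p = 1.  The exact null distribution is
    enumerated when the effective n is at most ``exact_max_n``; above
    that, a normal approximation with tie correction is used.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise DegenerateInputError("no differences supplied")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return _exact_two_sided_p(ranks, w_pos)
    # normal approximation with tie correction on the rank variance
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return 1.0
    z = (w_pos - mu) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def candidate_filter(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    timepoint: str,
    p_threshold: float = 0.001,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Merit table of candidate biomarker sites at one timepoint.

    Retains probes with merit > 0 whose paired Wilcoxon signed-rank p is
    below ``p_threshold``; ranked by merit descending with ties broken
    by probe id.  Probes with fewer than ``min_pairs`` complete pairs
    are dropped (logged).
    """
    pairs = pair_samples(sheet, timepoint)
    ab_cols = [p.ab for p in pairs]
    om_cols = [p.om for p in pairs]
    ab = matrix.data[ab_cols].to_numpy(dtype=float)
    om = matrix.data[om_cols].to_numpy(dtype=float)
    complete = ~np.isnan(ab) & ~np.isnan(om)
    n_pairs = complete.sum(axis=1)
    enough = n_pairs >= max(min_pairs, 2)
    n_dropped = int((~enough).sum())
    if n_dropped:
        logger.info("candidate_filter: dropped %d probes with < %d complete pairs",
                    n_dropped, min_pairs)

    with np.errstate(invalid="ignore"):
        med_ab = np.nanmedian(np.where(np.isnan(ab), np.nan, ab), axis=1)
        med_om = np.nanmedian(np.where(np.isnan(om), np.nan, om), axis=1)
        sd_ab = np.nanstd(ab, axis=1, ddof=1)
        sd_om = np.nanstd(om, axis=1, ddof=1)
        mean_ab = np.nanmean(ab, axis=1)
        mean_om = np.nanmean(om, axis=1)
    merit = np.abs(med_ab - med_om) - (sd_ab + sd_om)

    probe_ids = np.asarray(matrix.probe_ids)
    rows = []
    diff = np.where(complete, ab - om, np.nan)
    for i in np.nonzero(enough & (merit > 0.0))[0]:
        p = wilcoxon_signed_rank(diff[i])
        if p < p_threshold:
            rows.append(
                (probe_ids[i], float(merit[i]), p, float(mean_ab[i]),
                 float(mean_om[i]), int(n_pairs[i]))
            )
    out = pd.DataFrame(
        rows, columns=["probe_id", "merit", "wilcoxon_p", "mean_AB", "mean_OM", "n_pairs"]
    )
    out = out.sort_values(
        ["merit", "probe_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["timepoint"] = timepoint
    out.attrs["p_threshold"] = p_threshold
    out.attrs["n_positive_merit"] = int((enough & (merit > 0.0)).sum())
    out.attrs["n_dropped"] = n_dropped
    return out
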