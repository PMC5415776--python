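"""Paired differential-methylation stage.

Per-probe paired t tests between the AB and OM classes, Bonferroni
adjustment, signed delta-beta summaries, threshold binning and
two-timepoint overlap bookkeeping.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    BetaMatrix,
    DegenerateInputError,
    ParameterError,
    SampleSheet,
    m_transform,
    pair_samples,
)

logger = logging.getLogger(__name__)

DELTA_THRESHOLDS = (0.05, 0.10, 0.20, 0.50)


def paired_t_test(diffs: Sequence[float]) -> tuple[float, int, float]:
    """Classic one-sample t test on paired differences.

    Returns ``(t, df, p)`` with ``t = mean(d) / (sd(d) / sqrt(n))``,
    ``df = n - 1`` and a two-sided p value; the sample SD uses the n-1
    denominator.  Constant differences are degenerate.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[~np.isnan(d)]
    n = d.size
    if n < 2:
        raise DegenerateInputError(f"need >= 2 paired differences, got {n}")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise DegenerateInputError("zero variance in paired differences")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def bonferroni_adjust(p_raw: float, n_tests: int) -> float:
    """``min(1, p * n_tests)``."""
    if not 0.0 <= p_raw <= 1.0:
        raise ParameterError(f"p value out of [0, 1]: {p_raw}")
    if n_tests < 1:
        raise ParameterError(f"n_tests must be >= 1, got {n_tests}")
    return min(1.0, p_raw * n_tests)


def delta_beta(mean_ab: float, mean_om: float) -> float:
    """Signed class-mean difference, AB minus OM."""
    return mean_ab - mean_om


def diffmeth_table(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    timepoint: str,
    scale: str = "beta",
    min_pairs: int = 3,
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Per-probe paired t statistics for one timepoint.

    The test runs on beta values by default or on M-values with
    ``scale="mvalue"``; reported means and delta-beta are always on the
    beta scale.  Probes with fewer than ``min_pairs`` complete pairs or
    zero-variance differences are dropped (logged).  ``p_adjusted`` is
    Bonferroni over the number of probes actually tested.
    """
    if scale not in ("beta", "mvalue"):
        raise ParameterError(f"unknown scale {scale!r}")
    pairs = pair_samples(sheet, timepoint)
    if len(pairs) < 2:
        raise DegenerateInputError("need >= 2 complete AB/OM pairs")
    ab = matrix.data[[p.ab for p in pairs]].to_numpy(dtype=float)
    om = matrix.data[[p.om for p in pairs]].to_numpy(dtype=float)
    complete = ~np.isnan(ab) & ~np.isnan(om)
    n_pairs = complete.sum(axis=1)

    ab_c = np.where(complete, ab, np.nan)
    om_c = np.where(complete, om, np.nan)
    if scale == "beta":
        d = ab_c - om_c
    else:
        d = m_transform(ab_c, epsilon) - m_transform(om_c, epsilon)

    with np.errstate(invalid="ignore"):
        mean_d = np.nanmean(np.where(complete, d, np.nan), axis=1)
        sd_d = np.nanstd(np.where(complete, d, np.nan), axis=1, ddof=1)
        mean_ab = np.nanmean(ab_c, axis=1)
        mean_om = np.nanmean(om_c, axis=1)

    keep = (n_pairs >= max(min_pairs, 2)) & (sd_d > 0.0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("diffmeth: dropped %d probes (too few pairs or zero variance)",
                    n_dropped)

    n = n_pairs[keep].astype(float)
    t = mean_d[keep] / (sd_d[keep] / np.sqrt(n))
    df = n - 1
    p_raw = 2.0 * stats.t.sf(np.abs(t), df)
    n_tests = int(keep.sum())
    p_adj = np.minimum(1.0, p_raw * n_tests)

    out = pd.DataFrame(
        {
            "probe_id": np.asarray(matrix.probe_ids)[keep],
            "t_stat": t,
            "p_raw": p_raw,
            "p_adjusted": p_adj,
            "mean_AB": mean_ab[keep],
            "mean_OM": mean_om[keep],
            "delta_beta": mean_ab[keep] - mean_om[keep],
            "n_pairs": n_pairs[keep],
        }
    )
    out.attrs["n_tests"] = n_tests
    out.attrs["n_dropped"] = n_dropped
    out.attrs["timepoint"] = timepoint
    return out.reset_index(drop=True)


def significant_sites(records: pd.DataFrame, alpha_adjusted: float = 1e-7) -> pd.DataFrame:
    """Filter to adjusted p <= alpha; attach both rankings.

    ``rank_p`` orders by adjusted p ascending and ``rank_delta`` by
    absolute delta-beta descending; ties break on probe id so output is
    deterministic.
    """
    sig = records[records["p_adjusted"] <= alpha_adjusted].copy()
    if sig.empty:
        sig["rank_p"] = pd.Series(dtype=int)
        sig["rank_delta"] = pd.Series(dtype=int)
        return sig.reset_index(drop=True)
    sig = sig.sort_values(["p_adjusted", "probe_id"], kind="mergesort")
    sig["rank_p"] = np.arange(1, len(sig) + 1)
    by_delta = sig.assign(_abs=sig["delta_beta"].abs()).sort_values(
        ["_abs", "probe_id"], ascending=[False, True], kind="mergesort"
    )
    sig["rank_delta"] = pd.Series(np.arange(1, len(sig) + 1), index=by_delta.index)
    return sig.sort_values("rank_p", kind="mergesort").reset_index(drop=True)


def bin_by_delta(
    records: pd.DataFrame, thresholds: Iterable[float] = DELTA_THRESHOLDS
) -> pd.DataFrame:
    """Signed counts of sites at each absolute delta-beta threshold."""
    thresholds = sorted(thresholds)
    delta = records["delta_beta"].to_numpy(dtype=float) if len(records) else np.array([])
    rows = [
        {
            "threshold": 0.0,
            "n_positive": int((delta > 0).sum()),
            "n_negative": int((delta < 0).sum()),
            "n_total": int(delta.size),
        }
    ]
    for thr in thresholds:
        rows.append(
            {
                "threshold": thr,
                "n_positive": int((delta >= thr).sum()),
                "n_negative": int((delta <= -thr).sum()),
                "n_total": int((np.abs(delta) >= thr).sum()),
            }
        )
    return pd.DataFrame(rows)


def overlap_timepoints(
    before: pd.DataFrame, after: pd.DataFrame, widen_min: float = 0.05
) -> pd.DataFrame:
    """Probes significant at both timepoints, with widening flags.

    A probe is flagged ``widened`` when the absolute delta-beta grew by
    at least ``widen_min`` after weight loss.
    """
    cols = ["probe_id", "delta_beta"]
    merged = before[cols].merge(
        after[cols], on="probe_id", suffixes=("_before", "_after")
    )
    merged["widening"] = (
        merged["delta_beta_after"].abs() - merged["delta_beta_before"].abs()
    )
    merged["widened"] = merged["widening"] >= widen_min
    return merged.sort_values("probe_id", kind="mergesort").reset_index(drop=True)
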