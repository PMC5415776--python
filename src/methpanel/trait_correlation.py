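"""Correlation screen between per-individual tissue methylation
differences and clinical trait changes.

Sign conventions: delta-beta is AB minus OM for an individual's two
samples at one timepoint; delta-trait is before minus after (so weight
loss gives positive deltas for weight-like traits).  The screen filters
on raw two-sided p (no multiplicity correction).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    BetaMatrix,
    ClinicalTable,
    DegenerateInputError,
    SampleSheet,
    pair_samples,
)

logger = logging.getLogger(__name__)


def delta_trait(
    clinical: ClinicalTable, trait: str, individuals: Sequence[str] | None = None
) -> pd.Series:
    """Per-individual before - after change for one trait.

    Individuals missing either timepoint value are excluded (logged).
    """
    df = clinical.data[clinical.data["trait"] == trait]
    wide = df.pivot(index="individual_id", columns="timepoint", values="value")
    for tp in ("before", "after"):
        if tp not in wide.columns:
            wide[tp] = np.nan
    if individuals is not None:
        wide = wide.reindex(list(individuals))
    complete = wide["before"].notna() & wide["after"].notna()
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info("delta_trait(%s): excluded %d individuals missing a timepoint",
                    trait, n_excluded)
    out = (wide.loc[complete, "before"] - wide.loc[complete, "after"]).sort_index()
    out.name = trait
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-sided p from the t distribution.

    Implemented from the standard definition (not delegated) so it can
    be cross-checked against an independent oracle.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DegenerateInputError("inputs must be equal-length vectors")
    ok = ~np.isnan(xa) & ~np.isnan(ya)
    xa, ya = xa[ok], ya[ok]
    n = xa.size
    if n < 3:
        raise DegenerateInputError(f"need >= 3 complete observations, got {n}")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        raise DegenerateInputError("zero variance input")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def delta_beta_by_individual(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    timepoint: str,
    probes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-individual AB - OM beta difference (probes x individuals)."""
    pairs = pair_samples(sheet, timepoint)
    if not pairs:
        raise DegenerateInputError(f"no complete AB/OM pairs at {timepoint!r}")
    data = matrix.data if probes is None else matrix.subset_probes(list(probes)).data
    ab = data[[p.ab for p in pairs]].to_numpy(dtype=float)
    om = data[[p.om for p in pairs]].to_numpy(dtype=float)
    return pd.DataFrame(
        ab - om, index=data.index, columns=[p.individual_id for p in pairs]
    )


def correlation_screen(
    delta_betas: pd.DataFrame,
    delta_traits: Mapping[str, pd.Series] | pd.DataFrame,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """All probe x trait Pearson correlations passing ``p <= p_threshold``.

    ``delta_betas`` is probes x individuals; each trait series is
    indexed by individual.  Records are sorted by absolute r descending
    (ties by probe then trait).  Zero-variance probes are skipped.
    """
    if isinstance(delta_traits, pd.DataFrame):
        trait_map = {c: delta_traits[c] for c in delta_traits.columns}
    else:
        trait_map = dict(delta_traits)
    if delta_betas.empty or not trait_map:
        raise DegenerateInputError("need non-empty probe and trait sets")

    records = []
    for trait in sorted(trait_map):
        series = trait_map[trait].dropna()
        shared = [i for i in delta_betas.columns if i in series.index]
        if len(shared) < 3:
            raise DegenerateInputError(
                f"trait {trait!r}: fewer than 3 complete individuals"
            )
        x = delta_betas[shared].to_numpy(dtype=float)
        y = series.loc[shared].to_numpy(dtype=float)
        n = len(shared)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        sy = np.sqrt((yc**2).sum())
        sx = np.sqrt((xc**2).sum(axis=1))
        if sy == 0.0:
            raise DegenerateInputError(f"trait {trait!r} has zero variance")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.clip((xc @ yc) / (sx * sy), -1.0, 1.0)
        skip = sx == 0.0
        if skip.any():
            logger.info("correlation_screen: skipped %d zero-variance probes "
                        "for trait %s", int(skip.sum()), trait)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
        keep = ~skip & (p <= p_threshold)
        for i in np.nonzero(keep)[0]:
            records.append(
                (str(delta_betas.index[i]), trait, float(r[i]), float(p[i]), n)
            )
    out = pd.DataFrame(records, columns=["probe_id", "trait", "r", "p", "n"])
    out["abs_r"] = out["r"].abs()
    out = out.sort_values(
        ["abs_r", "probe_id", "trait"], ascending=[False, True, True], kind="mergesort"
    ).drop(columns="abs_r").reset_index(drop=True)
    return out
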