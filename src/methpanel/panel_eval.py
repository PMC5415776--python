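"""Panel evaluation: pairwise inter-sample scores and class separation.

For a panel of probes, every unordered sample pair gets a similarity
score ``1 - mean |beta_p - beta_q|``; a useful panel scores within-class
pairs strictly above between-class pairs (complete separation).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    BetaMatrix,
    DegenerateInputError,
    ParameterError,
    SampleSheet,
)

PAIR_TYPES = ("within_AB", "within_OM", "between")


def inter_sample_score(
    matrix: BetaMatrix, sample_p: str, sample_q: str, panel: Sequence[str]
) -> float:
    """Similarity of two samples over a probe panel, in [0, 1].

    Missing values are pairwise-deleted; an empty effective panel is an
    error.
    """
    sub = matrix.subset_probes(list(panel)).data
    p = sub[sample_p].to_numpy(dtype=float)
    q = sub[sample_q].to_numpy(dtype=float)
    diff = np.abs(p - q)
    ok = ~np.isnan(diff)
    if not ok.any():
        raise DegenerateInputError(
            f"no shared non-missing panel probes for {sample_p!r}, {sample_q!r}"
        )
    return float(1.0 - diff[ok].mean())


@dataclass(frozen=True)
class SeparationReport:
    """Within- vs between-class inter-sample score distributions."""

    panel: tuple[str, ...]
    pairs: pd.DataFrame  # sample_a, sample_b, score, pair_type
    min_within: float
    max_between: float
    complete_separation: bool
    histogram: pd.DataFrame  # bin_left, bin_right, counts per pair type
    bin_edges: tuple[float, ...]

    def summary(self) -> dict:
        return {
            "panel_size": len(self.panel),
            "n_pairs": int(len(self.pairs)),
            "min_within": self.min_within,
            "max_between": self.max_between,
            "complete_separation": self.complete_separation,
        }


def separation_report(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    panel: Sequence[str],
    timepoint: str | None = None,
    bins: int = 30,
) -> SeparationReport:
    """Score all sample pairs at a timepoint and summarize separation.

    ``complete_separation`` is strict: ties between the worst
    within-class pair and the best between-class pair count as overlap.
    """
    if bins < 1:
        raise ParameterError(f"bins must be >= 1, got {bins}")
    samples = sorted(
        s for s in sheet.samples(timepoint=timepoint) if s in matrix.data.columns
    )
    tissue = sheet.tissue_of()
    for t in ("AB", "OM"):
        if sum(tissue[s] == t for s in samples) < 2:
            raise DegenerateInputError(f"need >= 2 samples in class {t}")

    sub = matrix.subset_probes(list(panel)).data[samples]
    values = sub.to_numpy(dtype=float)
    rows = []
    for i, j in combinations(range(len(samples)), 2):
        diff = np.abs(values[:, i] - values[:, j])
        ok = ~np.isnan(diff)
        if not ok.any():
            raise DegenerateInputError(
                f"no shared non-missing panel probes for "
                f"{samples[i]!r}, {samples[j]!r}"
            )
        score = float(1.0 - diff[ok].mean())
        ta, tb = tissue[samples[i]], tissue[samples[j]]
        pair_type = f"within_{ta}" if ta == tb else "between"
        rows.append((samples[i], samples[j], score, pair_type))
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "score", "pair_type"])

    within = pairs.loc[pairs["pair_type"] != "between", "score"]
    between = pairs.loc[pairs["pair_type"] == "between", "score"]
    min_within = float(within.min())
    max_between = float(between.max())
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist = {"bin_left": edges[:-1], "bin_right": edges[1:]}
    for pt in PAIR_TYPES:
        scores = pairs.loc[pairs["pair_type"] == pt, "score"].to_numpy()
        hist[pt] = np.histogram(scores, bins=edges)[0]
    return SeparationReport(
        panel=tuple(panel),
        pairs=pairs,
        min_within=min_within,
        max_between=max_between,
        complete_separation=bool(max_between < min_within),
        histogram=pd.DataFrame(hist),
        bin_edges=tuple(float(e) for e in edges),
    )


def reduce_panel(shortlist: Sequence[str], k: int) -> list[str]:
    """Top-k prefix of a ranked shortlist."""
    shortlist = list(shortlist)
    if not 1 <= k <= len(shortlist):
        raise ParameterError(
            f"k must be in [1, {len(shortlist)}], got {k}"
        )
    return shortlist[:k]
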