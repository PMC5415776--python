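"""Red/blue dominating-set reduction of the candidate site list.

Candidates play both roles (red = potential dominators, blue = sites to
be covered), so the problem reduces to classical dominating set on the
cover graph.  A site covers another when their beta profiles across all
samples agree up to absolute Pearson correlation >= tau; redundant sites
are eliminated by selecting a minimum set of dominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import BetaMatrix, ParameterError

logger = logging.getLogger(__name__)

#: Largest instance solved exactly; larger instances fall back to greedy.
DEFAULT_EXACT_LIMIT = 20


@dataclass(frozen=True)
class CoverGraph:
    """Explicit site-covers-site relation over merit-ranked candidates.

    ``cover[i, j]`` is True when node ``i`` covers node ``j``; the
    diagonal is always True (every site covers itself).
    """

    nodes: tuple[str, ...]
    merit: tuple[float, ...]
    cover: np.ndarray
    tau: float

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if self.cover.shape != (n, n):
            raise ParameterError("cover matrix shape does not match node count")
        if not np.all(np.diagonal(self.cover)):
            raise ParameterError("every node must cover itself")

    def covered_counts(self) -> np.ndarray:
        return self.cover.sum(axis=1)

    def edge_list(self) -> pd.DataFrame:
        idx = np.argwhere(self.cover & ~np.eye(len(self.nodes), dtype=bool))
        rows = sorted((self.nodes[i], self.nodes[j]) for i, j in idx)
        return pd.DataFrame(rows, columns=["covering", "covered"])


def coverage_relation(
    matrix: BetaMatrix, candidates: pd.DataFrame, tau: float = 0.9
) -> CoverGraph:
    """Cover graph from absolute profile correlation across all samples.

    ``candidates`` is a merit table (``probe_id``, ``merit``, ranked);
    zero-variance probes cover only themselves (logged).
    """
    if candidates.empty:
        raise ParameterError("candidate table is empty")
    if not 0.0 < tau <= 1.0:
        raise ParameterError(f"tau must be in (0, 1], got {tau}")
    probes = list(candidates["probe_id"])
    profiles = matrix.subset_probes(probes).data.to_numpy(dtype=float)
    sd = profiles.std(axis=1)
    flat = sd == 0.0
    if flat.any():
        logger.info("coverage_relation: %d zero-variance probes cover only themselves",
                    int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(profiles)
    corr = np.nan_to_num(corr, nan=0.0)
    cover = np.abs(corr) >= tau
    cover[flat, :] = False
    cover[:, flat] = False
    np.fill_diagonal(cover, True)
    return CoverGraph(
        nodes=tuple(probes),
        merit=tuple(float(m) for m in candidates["merit"]),
        cover=cover,
        tau=tau,
    )


def _exact_min_dominating(masks: list[int], full: int) -> list[int]:
    """Exact minimum dominating set over bitmask neighbourhoods.

    A branch-and-bound pass (branching on the uncovered node with the
    fewest dominators) establishes the minimum cardinality; among all
    minimum-size solutions, the lexicographically smallest in node index
    order is returned.  Node order is merit order, so redundancy groups
    are represented by their highest-merit member.
    """
    from itertools import combinations

    n = len(masks)
    coverers = [[u for u in range(n) if masks[u] >> v & 1] for v in range(n)]
    best: list[int] = list(range(n))

    def rec(covered: int, chosen: list[int]) -> None:
        nonlocal best
        if covered == full:
            if len(chosen) < len(best):
                best = list(chosen)
            return
        if len(chosen) + 1 >= len(best):
            return
        pick, fewest = -1, n + 1
        v = 0
        rem = full & ~covered
        while rem:
            if rem & 1:
                k = len(coverers[v])
                if k < fewest:
                    pick, fewest = v, k
            rem >>= 1
            v += 1
        for u in coverers[pick]:
            chosen.append(u)
            rec(covered | masks[u], chosen)
            chosen.pop()

    rec(0, [])
    k = len(best)
    for subset in combinations(range(n), k):  # lexicographic order
        covered = 0
        for u in subset:
            covered |= masks[u]
        if covered == full:
            return list(subset)
    return best  # unreachable: best itself is feasible


def _greedy_dominating(masks: list[int], full: int) -> list[int]:
    """Greedy set cover: most newly covered first, ties to lower index
    (higher merit)."""
    n = len(masks)
    covered = 0
    chosen: list[int] = []
    while covered != full:
        gains = [(masks[u] | covered).bit_count() - covered.bit_count() for u in range(n)]
        u = int(np.argmax(gains))  # argmax takes the first maximum -> merit order
        if gains[u] == 0:  # cannot happen with self-cover, defensive
            raise RuntimeError("greedy domination stalled")
        chosen.append(u)
        covered |= masks[u]
    return chosen


def redblue_dominating_set(
    cover: CoverGraph, exact_limit: int = DEFAULT_EXACT_LIMIT
) -> pd.DataFrame:
    """Minimum (or greedy) set of sites dominating every candidate.

    Exact branch-and-bound when the instance has at most ``exact_limit``
    nodes, greedy set cover otherwise.  The returned shortlist preserves
    merit order and records how many candidates each dominator covers.
    """
    n = len(cover.nodes)
    masks = [0] * n
    for i in range(n):
        row = 0
        for j in np.nonzero(cover.cover[i])[0]:
            row |= 1 << int(j)
        masks[i] = row
    full = (1 << n) - 1
    if n <= exact_limit:
        chosen = _exact_min_dominating(masks, full)
        mode = "exact"
    else:
        chosen = _greedy_dominating(masks, full)
        mode = "greedy"

    union = 0
    for u in chosen:
        union |= masks[u]
    assert union == full, "dominating set infeasible (broken invariant)"

    chosen = sorted(chosen)  # node order is merit order already
    out = pd.DataFrame(
        {
            "probe_id": [cover.nodes[u] for u in chosen],
            "merit": [cover.merit[u] for u in chosen],
            "rank": np.arange(1, len(chosen) + 1),
            "covered_sites": [int(cover.cover[u].sum()) for u in chosen],
            "dominator": True,
        }
    )
    out.attrs["mode"] = mode
    out.attrs["tau"] = cover.tau
    out.attrs["n_candidates"] = n
    return out
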