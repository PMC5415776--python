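"""Sample-similarity graph, thresholding and clique homogeneity checks."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_model import BetaMatrix, ParameterError, SampleSheet, ValidationError


def build_sample_graph(matrix: BetaMatrix, panel: Sequence[str]) -> nx.Graph:
    """Complete weighted graph over the matrix samples.

    Edge weight is ``1 - mean |beta_p - beta_q|`` over the panel probes,
    with missing values pairwise-deleted.  A pair sharing no non-missing
    panel probe is an error.
    """
    panel = list(panel)
    if not panel:
        raise ParameterError("panel must be non-empty")
    sub = matrix.subset_probes(panel)
    values = sub.data.to_numpy(dtype=float)
    samples = list(sub.sample_ids)
    graph = nx.Graph()
    graph.add_nodes_from(samples)
    for i, j in combinations(range(len(samples)), 2):
        diff = np.abs(values[:, i] - values[:, j])
        ok = ~np.isnan(diff)
        if not ok.any():
            raise ValidationError(
                f"samples {samples[i]!r} and {samples[j]!r} share no "
                "non-missing panel probes"
            )
        graph.add_edge(samples[i], samples[j], weight=float(1.0 - diff[ok].mean()))
    return graph


def threshold_graph(graph: nx.Graph, t: float) -> nx.Graph:
    """Keep edges with weight >= t; vertex set unchanged."""
    if not 0.0 <= t <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {t}")
    out = nx.Graph()
    out.add_nodes_from(graph.nodes)
    out.add_edges_from(
        (u, v, d) for u, v, d in graph.edges(data=True) if d["weight"] >= t
    )
    out.graph["threshold"] = t
    return out


def suggest_threshold(graph: nx.Graph, sheet: SampleSheet) -> float:
    """Midpoint of the mean within-class and mean between-class weights."""
    tissue = sheet.tissue_of()
    within, between = [], []
    for u, v, d in graph.edges(data=True):
        (within if tissue[u] == tissue[v] else between).append(d["weight"])
    if not within or not between:
        raise ParameterError("need both within- and between-class edges")
    return float((np.mean(within) + np.mean(between)) / 2.0)


def maximal_cliques(graph: nx.Graph) -> list[tuple[str, ...]]:
    """All maximal cliques (Bron-Kerbosch with pivoting), each emitted
    once, ordered by size descending then lexicographic membership."""
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    return sorted(cliques, key=lambda c: (-len(c), c))


@dataclass(frozen=True)
class HomogeneityReport:
    """Per-clique tissue homogeneity verdicts and the overall gate."""

    records: pd.DataFrame
    min_size: int
    overall_pass: bool


def homogeneity_check(
    cliques: Sequence[Sequence[str]], sheet: SampleSheet, min_size: int = 3
) -> HomogeneityReport:
    """A clique is homogeneous iff all members share a tissue class.

    The overall gate passes when every clique of size >= ``min_size`` is
    homogeneous (smaller cliques are reported but not gating).
    """
    tissue = sheet.tissue_of()
    rows = []
    overall = True
    for clique in cliques:
        members = tuple(sorted(clique))
        classes = sorted({tissue[m] for m in members})
        homogeneous = len(classes) == 1
        if len(members) >= min_size and not homogeneous:
            overall = False
        rows.append(
            {
                "members": ",".join(members),
                "size": len(members),
                "classes": ",".join(classes),
                "homogeneous": homogeneous,
                "gating": len(members) >= min_size,
            }
        )
    records = pd.DataFrame(
        rows, columns=["members", "size", "classes", "homogeneous", "gating"]
    )
    return HomogeneityReport(records=records, min_size=min_size, overall_pass=overall)


def export_edge_list(graph: nx.Graph, path, sep: str = "\t") -> None:
    rows = sorted(
        (min(u, v), max(u, v), d.get("weight", np.nan))
        for u, v, d in graph.edges(data=True)
    )
    pd.DataFrame(rows, columns=["sample_a", "sample_b", "weight"]).to_csv(
        path, sep=sep, index=False, float_format="%.12g"
    )
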