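"""End-to-end orchestration of the discovery and differential stages.

Every run writes its serialized config, a machine-readable JSON summary
with per-stage counts, and deterministic delimited tables, so a run can
be reproduced bit-identically from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import biomarker_merit, diffmeth, panel_eval, redblue_domset, sample_graph
from .data_model import (
    BetaMatrix,
    ParameterError,
    ProbeAnnotation,
    SampleSheet,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    timepoint: str = "before"
    p_wilcoxon: float = 0.001
    min_pairs: int = 3
    panel_m: int = 100
    graph_threshold: float | None = None  # None -> midpoint heuristic
    min_clique_size: int = 3
    tau: float = 0.9
    exact_limit: int = redblue_domset.DEFAULT_EXACT_LIMIT
    top_ks: tuple[int, ...] = (10, 1)
    bins: int = 30
    alpha_adjusted: float = 1e-7
    widen_min: float = 0.05
    scale: str = "beta"
    seed: int = 0

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def _write_separation(report: panel_eval.SeparationReport, out_dir: Path, tag: str) -> None:
    _write(report.pairs, out_dir / f"separation_{tag}_pairs.tsv")
    _write(report.histogram, out_dir / f"separation_{tag}_hist.tsv")
    with open(out_dir / f"separation_{tag}_summary.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def annotate_probes(df: pd.DataFrame, annotation: ProbeAnnotation | None) -> pd.DataFrame:
    """Attach gene / region / locus columns when an annotation is given."""
    if annotation is None or df.empty and "probe_id" not in df.columns:
        return df
    ann = annotation.data.assign(
        locus=annotation.locus_labels().to_numpy()
    )[["probe_id", "gene", "region", "locus"]]
    return df.merge(ann, on="probe_id", how="left")


def run_discovery(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    config: RunConfig,
    out_dir,
    annotation: ProbeAnnotation | None = None,
) -> dict:
    """Merit filter -> homogeneity gate -> domination -> separation.

    Returns the run summary (also written to ``run_summary.json``).  A
    failed homogeneity gate does not stop the pipeline; it is recorded
    in the summary so callers can distinguish the exit status.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    summary: dict = {
        "timepoint": config.timepoint,
        "seed": config.seed,
        "n_probes": matrix.shape[0],
        "n_samples": matrix.shape[1],
    }

    merit = biomarker_merit.candidate_filter(
        matrix, sheet, config.timepoint,
        p_threshold=config.p_wilcoxon, min_pairs=config.min_pairs,
    )
    _write(annotate_probes(merit, annotation), out_dir / "merit_table.tsv")
    summary["n_positive_merit"] = merit.attrs.get("n_positive_merit", len(merit))
    summary["n_candidates"] = len(merit)

    if merit.empty:
        logger.warning("no candidates passed filtering; writing empty outputs")
        summary.update(
            {"homogeneity_pass": None, "n_shortlist": 0, "panels": {}}
        )
        _write(pd.DataFrame(columns=["probe_id", "merit", "rank"]),
               out_dir / "shortlist.tsv")
        with open(out_dir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return summary

    # diagnostic gate: similarity graph over this timepoint's samples
    tp_samples = sheet.samples(timepoint=config.timepoint)
    tp_matrix = matrix.subset_samples(tp_samples)
    panel = list(merit["probe_id"].iloc[: config.panel_m])
    graph = sample_graph.build_sample_graph(tp_matrix, panel)
    threshold = (
        config.graph_threshold
        if config.graph_threshold is not None
        else sample_graph.suggest_threshold(graph, sheet)
    )
    thresholded = sample_graph.threshold_graph(graph, threshold)
    cliques = sample_graph.maximal_cliques(thresholded)
    homogeneity = sample_graph.homogeneity_check(
        cliques, sheet, min_size=config.min_clique_size
    )
    sample_graph.export_edge_list(graph, out_dir / "sample_graph_edges.tsv")
    sample_graph.export_edge_list(thresholded, out_dir / "sample_graph_thresholded.tsv")
    _write(homogeneity.records, out_dir / "clique_homogeneity.tsv")
    summary["graph_threshold"] = float(threshold)
    summary["n_cliques"] = len(cliques)
    summary["homogeneity_pass"] = homogeneity.overall_pass
    if not homogeneity.overall_pass:
        logger.warning("clique homogeneity gate FAILED; continuing, flagged in summary")

    cover = redblue_domset.coverage_relation(matrix, merit, tau=config.tau)
    shortlist = redblue_domset.redblue_dominating_set(
        cover, exact_limit=config.exact_limit
    )
    _write(cover.edge_list(), out_dir / "cover_edges.tsv")
    _write(annotate_probes(shortlist, annotation), out_dir / "shortlist.tsv")
    summary["n_shortlist"] = len(shortlist)
    summary["domset_mode"] = shortlist.attrs.get("mode")
    summary["tau"] = config.tau

    panels = {"full": list(shortlist["probe_id"])}
    for k in config.top_ks:
        if 1 <= k <= len(shortlist):
            panels[f"top{k}"] = panel_eval.reduce_panel(list(shortlist["probe_id"]), k)
    summary["panels"] = {}
    for tag, probe_panel in panels.items():
        report = panel_eval.separation_report(
            matrix, sheet, probe_panel,
            timepoint=config.timepoint, bins=config.bins,
        )
        _write_separation(report, out_dir, tag)
        summary["panels"][tag] = report.summary()

    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def run_diffmeth_compare(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    config: RunConfig,
    out_dir,
    annotation: ProbeAnnotation | None = None,
) -> dict:
    """Per-timepoint significant-site tables plus overlap bookkeeping.

    Adds a ``biomarker_rank`` cross-reference column (NA when a site was
    not seen by the merit filter at that timepoint).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    timepoints = ("before", "after")
    for tp in timepoints:
        if not sheet.samples(timepoint=tp):
            raise ParameterError(f"sample sheet has no samples at timepoint {tp!r}")

    summary: dict = {"seed": config.seed, "alpha_adjusted": config.alpha_adjusted}
    significant: dict[str, pd.DataFrame] = {}
    for tp in timepoints:
        records = diffmeth.diffmeth_table(
            matrix, sheet, tp, scale=config.scale, min_pairs=config.min_pairs
        )
        sig = diffmeth.significant_sites(records, config.alpha_adjusted)
        merit = biomarker_merit.candidate_filter(
            matrix, sheet, tp, p_threshold=config.p_wilcoxon,
            min_pairs=config.min_pairs,
        )
        rank_map = dict(zip(merit["probe_id"], merit["rank"]))
        sig["biomarker_rank"] = [
            rank_map.get(p, pd.NA) for p in sig["probe_id"]
        ]
        significant[tp] = sig
        _write(annotate_probes(sig, annotation), out_dir / f"significant_{tp}.tsv")
        _write(diffmeth.bin_by_delta(sig), out_dir / f"delta_bins_{tp}.tsv")
        summary[f"n_tested_{tp}"] = records.attrs["n_tests"]
        summary[f"n_significant_{tp}"] = len(sig)

    overlap = diffmeth.overlap_timepoints(
        significant["before"], significant["after"], widen_min=config.widen_min
    )
    _write(overlap, out_dir / "overlap.tsv")
    summary["n_overlap"] = len(overlap)
    summary["n_widened"] = int(overlap["widened"].sum()) if len(overlap) else 0

    with open(out_dir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
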