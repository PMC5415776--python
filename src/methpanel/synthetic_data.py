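"""Synthetic paired two-tissue, two-timepoint methylation cohorts.

Generates bounded, bimodal, within-individual-correlated beta values
with configurable ground truth: tissue-discriminating probes at chosen
delta-beta levels, an optional SNP-disrupted trimodal probe, and
clinical traits whose before/after change tracks a chosen probe's
per-individual delta-beta at a target correlation.

Observation model: per probe a baseline mean is drawn from a two-mode
mixture; per individual a logit-scale random effect is shared across all
of that individual's samples; each observation is a draw from a beta
distribution with the resulting mean and a common concentration.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    BetaMatrix,
    ClinicalTable,
    ParameterError,
    ProbeAnnotation,
    SampleSheet,
    TIMEPOINTS,
    TISSUES,
)

MEAN_CLIP = (0.02, 0.98)  # keeps beta parameters away from degeneracy


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def _invlogit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SnpProbeSpec:
    """Trimodal probe driven by an individual's genotype at a nearby SNP."""

    allele_freq: float
    meth_by_genotype: tuple[float, float, float] = (0.95, 0.5, 0.05)

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_freq < 1.0:
            raise ParameterError("allele_freq must be in (0, 1)")
        if any(not 0.0 < m < 1.0 for m in self.meth_by_genotype):
            raise ParameterError("genotype methylation levels must be in (0, 1)")


@dataclass(frozen=True)
class TraitSpec:
    """Trait whose before-after change correlates with a probe's
    per-individual delta-beta at ``target_r``.

    ``noise_sd`` scales a residual calibrated so the asymptotic
    correlation equals ``target_r`` at ``noise_sd = 1``; as it shrinks
    to 0 the empirical correlation tends to +-1.
    """

    name: str
    probe_id: str
    target_r: float
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_r <= 1.0:
            raise ParameterError("|target_r| must be <= 1")
        if self.target_r == 0.0:
            raise ParameterError("target_r must be non-zero")
        if self.noise_sd < 0.0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 15
    n_probes: int = 1000
    n_discriminating: int = 20
    delta_levels: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5)
    precision: float = 150.0
    individual_sd: float = 0.3
    baseline_mix: tuple[float, float, float] = (0.15, 0.85, 0.5)
    baseline_logit_sd: float = 0.6
    delta_widening: float = 1.3
    snp_probe: SnpProbeSpec | None = None
    trait_specs: tuple[TraitSpec, ...] = ()
    timepoints: tuple[str, ...] = TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        low, high, weight = self.baseline_mix
        if not (0.0 < low < 1.0 and 0.0 < high < 1.0):
            raise ParameterError("baseline modes must be in (0, 1)")
        if not 0.0 <= weight <= 1.0:
            raise ParameterError("mixing weight must be in [0, 1]")
        if self.n_discriminating > self.n_probes:
            raise ParameterError("n_discriminating cannot exceed n_probes")
        if self.n_individuals < 1 or self.n_probes < 1:
            raise ParameterError("cohort dimensions must be positive")
        if self.precision <= 0.0:
            raise ParameterError("precision must be > 0")
        if self.individual_sd < 0.0:
            raise ParameterError("individual_sd must be >= 0")
        if self.delta_widening <= 0.0:
            raise ParameterError("delta_widening must be > 0")
        span = MEAN_CLIP[1] - MEAN_CLIP[0]
        for level in self.delta_levels:
            if not 0.0 < level < span:
                raise ParameterError(
                    f"delta level {level} infeasible within mean clip {MEAN_CLIP}"
                )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        data = dict(mapping)
        if "snp_probe" in data and data["snp_probe"] is not None:
            snp = dict(data["snp_probe"])
            if "meth_by_genotype" in snp:
                snp["meth_by_genotype"] = tuple(snp["meth_by_genotype"])
            data["snp_probe"] = SnpProbeSpec(**snp)
        if "trait_specs" in data:
            data["trait_specs"] = tuple(
                TraitSpec(**dict(t)) for t in data["trait_specs"]
            )
        for key in ("delta_levels", "baseline_mix", "timepoints"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


Cohort = namedtuple("Cohort", ["beta", "sheet", "annotation", "clinical", "truth"])


def _probe_id(i: int) -> str:
    return f"cg{i:08d}"


def _individual_id(i: int) -> str:
    return f"I{i:03d}"


def _sample_id(ind: str, tissue: str, timepoint: str) -> str:
    return f"{ind}_{tissue}_{timepoint}"


def _draw_baselines(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    low, high, weight = cfg.baseline_mix
    modes = np.where(rng.random(cfg.n_probes) < weight, low, high)
    jitter = rng.normal(0.0, cfg.baseline_logit_sd, cfg.n_probes)
    return np.clip(_invlogit(_logit(modes) + jitter), *MEAN_CLIP)


def _discriminating_means(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, dict[int, np.ndarray]]]:
    """Pick discriminating probes and build per-(tissue, timepoint) means.

    Discriminating probe k gets signed delta ``+-delta_levels[k % len]``
    (AB minus OM on the mean scale), widened by ``delta_widening`` at
    the second timepoint; the AB mean is drawn from the interval keeping
    both class means inside the clip range for the widest delta.
    """
    disc = np.sort(rng.choice(cfg.n_probes, size=cfg.n_discriminating, replace=False))
    levels = np.array(
        [cfg.delta_levels[k % len(cfg.delta_levels)] for k in range(cfg.n_discriminating)]
    )
    signs = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(cfg.n_discriminating)])
    deltas = {"before": signs * levels}
    lo, hi = MEAN_CLIP
    widest = levels * max(1.0, cfg.delta_widening)
    # feasible AB interval for the widest signed delta
    ab_lo = np.maximum(lo, lo + signs * widest)
    ab_hi = np.minimum(hi, hi + signs * widest)
    infeasible = ab_hi - ab_lo <= 0.01
    if infeasible.any():
        raise ParameterError(
            "delta levels push class means outside the clip range after widening"
        )
    ab_mean = rng.uniform(ab_lo + 0.005, ab_hi - 0.005)
    if len(cfg.timepoints) > 1:
        deltas[cfg.timepoints[1]] = np.clip(
            signs * levels * cfg.delta_widening, ab_mean - hi, ab_mean - lo
        )
    return disc, {"ab_mean": ab_mean, "deltas": deltas}


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate a full paired cohort with ground truth.

    Deterministic for a fixed seed.  Returns beta matrix, sample sheet,
    probe annotation, clinical table and a truth table recording each
    probe's class means and realized mean-scale delta per timepoint.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_probes, n_ind = cfg.n_probes, cfg.n_individuals
    probes = [_probe_id(i) for i in range(n_probes)]
    individuals = [_individual_id(i) for i in range(n_ind)]
    timepoints = tuple(cfg.timepoints)

    baseline = _draw_baselines(cfg, rng)
    disc_idx, disc = _discriminating_means(cfg, rng)
    is_disc = np.zeros(n_probes, dtype=bool)
    is_disc[disc_idx] = True

    # per-(tissue, timepoint) mean matrix, AB = baseline for non-disc probes
    means: dict[tuple[str, str], np.ndarray] = {}
    lo, hi = MEAN_CLIP
    for tp in timepoints:
        ab = baseline.copy()
        om = baseline.copy()
        delta = disc["deltas"].get(tp, disc["deltas"]["before"])
        ab[disc_idx] = disc["ab_mean"]
        om[disc_idx] = np.clip(disc["ab_mean"] - delta, lo, hi)
        means[("AB", tp)] = ab
        means[("OM", tp)] = om

    # optional SNP-driven trimodal probe: overrides one non-disc probe
    snp_idx = None
    genotypes = None
    if cfg.snp_probe is not None:
        non_disc = np.setdiff1d(np.arange(n_probes), disc_idx)
        if non_disc.size == 0:
            raise ParameterError("no free probe available for the SNP probe")
        snp_idx = int(non_disc[0])
        genotypes = rng.binomial(2, cfg.snp_probe.allele_freq, size=n_ind)

    effects = rng.normal(0.0, cfg.individual_sd, size=n_ind)

    sheet_rows = []
    columns: dict[str, np.ndarray] = {}
    for tp in timepoints:
        for tissue in TISSUES:
            mu_class = means[(tissue, tp)]
            for i, ind in enumerate(individuals):
                mu = _invlogit(_logit(mu_class) + effects[i])
                if snp_idx is not None:
                    g = int(genotypes[i])
                    level = cfg.snp_probe.meth_by_genotype[g]
                    mu[snp_idx] = _invlogit(np.log(level / (1 - level)) + effects[i])
                mu = np.clip(mu, 0.005, 0.995)
                a = mu * cfg.precision
                b = (1.0 - mu) * cfg.precision
                sid = _sample_id(ind, tissue, tp)
                columns[sid] = rng.beta(a, b)
                sheet_rows.append((sid, ind, tissue, tp))

    beta = BetaMatrix(pd.DataFrame(columns, index=pd.Index(probes, name="probe_id")))
    sheet = SampleSheet(
        pd.DataFrame(sheet_rows, columns=["sample_id", "individual_id", "tissue", "timepoint"])
    )

    chroms = [str(1 + i % 22) for i in range(n_probes)]
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": probes,
                "chromosome": chroms,
                "position": 1000 + 137 * np.arange(n_probes),
                "gene": [
                    f"GENE{i // 5}" if i % 3 else "Intergenic" for i in range(n_probes)
                ],
                "region": [
                    ("Body", "TSS1500", "TSS200", "5'UTR", "1stExon")[i % 5]
                    for i in range(n_probes)
                ],
                "snp_flag": [snp_idx is not None and i == snp_idx for i in range(n_probes)],
            }
        )
    )

    truth_rows = {
        "probe_id": probes,
        "discriminating": is_disc,
        "snp_probe": [snp_idx is not None and i == snp_idx for i in range(n_probes)],
    }
    for tp in timepoints:
        truth_rows[f"mean_AB_{tp}"] = means[("AB", tp)]
        truth_rows[f"mean_OM_{tp}"] = means[("OM", tp)]
        truth_rows[f"delta_{tp}"] = means[("AB", tp)] - means[("OM", tp)]
    truth = pd.DataFrame(truth_rows)

    clinical = _simulate_traits(cfg, beta, sheet, rng)
    return Cohort(beta, sheet, annotation, clinical, truth)


def _simulate_traits(
    cfg: SimConfig, beta: BetaMatrix, sheet: SampleSheet, rng: np.random.Generator
) -> ClinicalTable:
    """Build trait tables from the realized per-individual delta-betas.

    delta-trait = r * z + noise_sd * sqrt(1 - r^2) * eps with z the
    standardized delta-beta of the target probe at the last timepoint,
    so the asymptotic correlation is r / sqrt(r^2 + noise_sd^2 (1-r^2)):
    exactly r at noise_sd = 1 and +-1 as noise_sd -> 0.
    """
    from .trait_correlation import delta_beta_by_individual  # local: avoid cycle

    rows = []
    tp = cfg.timepoints[-1]
    for spec in cfg.trait_specs:
        if spec.probe_id not in beta.data.index:
            raise ParameterError(f"trait target probe {spec.probe_id!r} not simulated")
        z = delta_beta_by_individual(beta, sheet, tp, probes=[spec.probe_id]).iloc[0]
        sd = z.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ParameterError(
                f"target probe {spec.probe_id!r} has zero delta-beta variance"
            )
        z_std = (z - z.mean()) / sd
        eps = rng.normal(0.0, 1.0, size=len(z_std))
        resid_scale = spec.noise_sd * np.sqrt(max(1.0 - spec.target_r**2, 0.0))
        delta = spec.target_r * z_std.to_numpy() + resid_scale * eps
        for ind, d in zip(z_std.index, delta):
            rows.append((ind, spec.name, "after", 0.0))
            rows.append((ind, spec.name, "before", float(d)))
    if not rows:
        rows = []  # empty but schema-valid
    clinical = pd.DataFrame(
        rows, columns=["individual_id", "trait", "timepoint", "value"]
    )
    return ClinicalTable(clinical)


def inject_perfect_marker(
    matrix: BetaMatrix,
    sheet: SampleSheet,
    probe_id: str,
    low: float,
    high: float,
    rng: np.random.Generator | int | None = 0,
) -> BetaMatrix:
    """Overwrite one probe with a fully tissue-discriminating profile.

    AB samples get values uniform in ``[low - 0.02, low + 0.02]`` and OM
    samples in ``[high - 0.02, high + 0.02]`` (both clipped to [0, 1]);
    the class supports are disjoint only when ``high - low > 0.04``, so
    anything narrower is rejected.
    """
    if not high - low > 0.04:
        raise ParameterError(
            f"target ranges overlap: low={low}, high={high} (need high - low > 0.04)"
        )
    if probe_id not in matrix.data.index:
        raise ParameterError(f"probe {probe_id!r} not in matrix")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    tissue = sheet.tissue_of()
    data = matrix.data.copy()
    for sid in data.columns:
        centre = low if tissue.get(sid) == "AB" else high
        lo = max(0.0, centre - 0.02)
        hi = min(1.0, centre + 0.02)
        data.loc[probe_id, sid] = rng.uniform(lo, hi)
    return BetaMatrix(data)
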