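"""Domain types and delimited-text I/O for paired methylation cohorts.

All tabular formats are plain text with a header row and a configurable
delimiter (tab by default); the missing-value token is ``"NA"``.  Beta
values are methylation fractions in ``[0, 1]``, stored probes-as-rows and
samples-as-columns.  Coordinates in probe annotations are 1-based
(GRCh37 / manifest convention).
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("AB", "OM")
TIMEPOINTS = ("before", "after")
NA_TOKEN = "NA"

#: Columns expected in a sample sheet file.
SHEET_COLUMNS = ("sample_id", "individual_id", "tissue", "timepoint")
#: Columns expected in a clinical trait file.
CLINICAL_COLUMNS = ("individual_id", "trait", "timepoint", "value")
#: Columns expected in a probe annotation file.
ANNOTATION_COLUMNS = ("probe_id", "chromosome", "position", "gene", "region", "snp_flag")

#: Gene field value that encodes "no gene annotation".
INTERGENIC = "Intergenic"


class FormatError(ValueError):
    """Malformed input file (bad header, non-numeric cell, missing column)."""


class ValidationError(ValueError):
    """Structurally readable input that violates a domain invariant."""


class ParameterError(ValueError):
    """Out-of-range argument to an operation."""


class DegenerateInputError(ValueError):
    """Input too small or too flat for the requested statistic."""


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BetaMatrix:
    """Probes x samples matrix of methylation fractions in ``[0, 1]``.

    Missing values are ``NaN``.  The wrapped :class:`pandas.DataFrame` is
    indexed by probe id with sample ids as columns; both must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate probe ids: {dups[:5]}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric beta value: {exc}") from exc
        if df.to_numpy().dtype != float:
            df = df.astype(float)
            object.__setattr__(self, "data", df)
        with np.errstate(invalid="ignore"):
            bad = (values < 0.0) | (values > 1.0)
        bad &= ~np.isnan(values)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"beta value out of [0, 1] at probe {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {values[i, j]}"
            )

    # -- accessors ----------------------------------------------------------

    @property
    def probe_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probes: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probes if p not in self.data.index]
        if missing:
            raise ValidationError(f"probes not in matrix: {missing[:5]}")
        return BetaMatrix(self.data.loc[list(probes)])

    def subset_samples(self, samples: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in samples if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing[:5]}")
        return BetaMatrix(self.data[list(samples)])


def read_beta_matrix(path, sep: str = "\t") -> BetaMatrix:
    """Read a beta matrix from delimited text.

    First column holds probe ids, header row holds sample ids, ``"NA"``
    encodes missing.  Values outside ``[0, 1]`` raise
    :class:`ValidationError` naming the offending probe and sample.
    """
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, na_values=[NA_TOKEN], keep_default_na=False
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse beta matrix {path}: {exc}") from exc
    if df.columns.size == 0:
        raise FormatError(f"beta matrix {path} has no sample columns")
    if any(str(c).startswith("Unnamed:") for c in df.columns):
        raise FormatError(f"beta matrix {path} has unnamed header fields")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(matrix: BetaMatrix, path, sep: str = "\t") -> None:
    matrix.data.to_csv(path, sep=sep, na_rep=NA_TOKEN, index_label="probe_id",
                       float_format="%.12g")


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSheet:
    """Maps samples to (individual, tissue class, timepoint).

    At most one sample per (individual, tissue, timepoint) and each
    sample id appears in exactly one row.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        df = df[list(SHEET_COLUMNS)].astype(str).reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in sheet: {dups[:5]}")
        bad_tissue = sorted(set(df["tissue"]) - set(TISSUES))
        if bad_tissue:
            raise ValidationError(f"unknown tissue classes: {bad_tissue}")
        bad_tp = sorted(set(df["timepoint"]) - set(TIMEPOINTS))
        if bad_tp:
            raise ValidationError(f"unknown timepoints: {bad_tp}")
        key = df[["individual_id", "tissue", "timepoint"]]
        if key.duplicated().any():
            raise ValidationError(
                "more than one sample for the same (individual, tissue, timepoint)"
            )
        object.__setattr__(self, "data", df)

    def samples(self, tissue: str | None = None, timepoint: str | None = None) -> list[str]:
        """Sample ids matching the given tissue/timepoint, sorted."""
        df = self.data
        if tissue is not None:
            df = df[df["tissue"] == tissue]
        if timepoint is not None:
            df = df[df["timepoint"] == timepoint]
        return sorted(df["sample_id"])

    def tissue_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["tissue"]))

    def individual_of(self) -> dict[str, str]:
        return dict(zip(self.data["sample_id"], self.data["individual_id"]))

    @property
    def individuals(self) -> list[str]:
        return sorted(self.data["individual_id"].unique())


def read_sample_sheet(path, sep: str = "\t") -> SampleSheet:
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=[NA_TOKEN],
                     keep_default_na=False)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path, sep: str = "\t") -> None:
    sheet.data.to_csv(path, sep=sep, index=False)


Pair = namedtuple("Pair", ["individual_id", "ab", "om"])


def pair_samples(sheet: SampleSheet, timepoint: str) -> list[Pair]:
    """AB/OM sample pairs per individual at one timepoint.

    Individuals lacking either tissue at that timepoint are skipped (and
    logged).  Output is sorted by individual id.
    """
    if timepoint not in TIMEPOINTS:
        raise ParameterError(f"unknown timepoint {timepoint!r}")
    df = sheet.data[sheet.data["timepoint"] == timepoint]
    by_ind: dict[str, dict[str, str]] = {}
    for row in df.itertuples(index=False):
        by_ind.setdefault(row.individual_id, {})[row.tissue] = row.sample_id
    pairs = []
    for ind in sorted(by_ind):
        tissues = by_ind[ind]
        if "AB" in tissues and "OM" in tissues:
            pairs.append(Pair(ind, tissues["AB"], tissues["OM"]))
        else:
            logger.info("individual %s lacks a complete AB/OM pair at %s; skipped",
                        ind, timepoint)
    return pairs


# ---------------------------------------------------------------------------
# ProbeAnnotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeAnnotation:
    """Manifest-style probe annotation: chromosome, 1-based position, gene,
    region feature and SNP flag.  ``"Intergenic"`` encodes absent gene
    annotation."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"probe annotation missing columns: {missing}")
        df = df[list(ANNOTATION_COLUMNS)].reset_index(drop=True)
        if df["probe_id"].duplicated().any():
            raise ValidationError("duplicate probe ids in annotation")
        df["position"] = df["position"].astype(int)
        if (df["position"] < 1).any():
            raise ValidationError("probe annotation positions must be >= 1")
        df["snp_flag"] = df["snp_flag"].astype(bool)
        df["gene"] = df["gene"].fillna(INTERGENIC).replace("", INTERGENIC)
        object.__setattr__(self, "data", df)

    def locus_labels(self) -> pd.Series:
        """``chromosome:position`` label per probe, indexed by probe id."""
        df = self.data
        return pd.Series(
            df["chromosome"].astype(str) + ":" + df["position"].astype(str),
            index=df["probe_id"],
        )


def read_probe_annotation(path, sep: str = "\t") -> ProbeAnnotation:
    df = pd.read_csv(path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False)
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path, sep: str = "\t") -> None:
    annotation.data.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# ClinicalTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalTable:
    """Long-format clinical traits: one value per
    (individual, trait, timepoint)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"clinical table missing columns: {missing}")
        df = df[list(CLINICAL_COLUMNS)].reset_index(drop=True)
        bad_tp = sorted(set(df["timepoint"].astype(str)) - set(TIMEPOINTS))
        if bad_tp:
            raise ValidationError(f"unknown timepoints in clinical table: {bad_tp}")
        key = df[["individual_id", "trait", "timepoint"]]
        if key.duplicated().any():
            raise ValidationError(
                "more than one value for the same (individual, trait, timepoint)"
            )
        df["value"] = df["value"].astype(float)
        object.__setattr__(self, "data", df)

    @property
    def traits(self) -> list[str]:
        return sorted(self.data["trait"].unique())


def read_clinical_table(path, sep: str = "\t") -> ClinicalTable:
    df = pd.read_csv(path, sep=sep, na_values=[NA_TOKEN], keep_default_na=False)
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Elementary transforms
# ---------------------------------------------------------------------------


def m_transform(beta, epsilon: float = 1e-6):
    """Logit2 transform of beta values: ``log2(b / (1 - b))``.

    Values are clipped into ``[epsilon, 1 - epsilon]`` first so the
    transform is finite at the boundaries.  Accepts scalars or arrays.
    """
    if not 0.0 < epsilon < 0.5:
        raise ParameterError(f"epsilon must be in (0, 0.5), got {epsilon}")
    arr = np.asarray(beta, dtype=float)
    clipped = np.clip(arr, epsilon, 1.0 - epsilon)
    out = np.log2(clipped / (1.0 - clipped))
    out = np.where(np.isnan(arr), np.nan, out)
    if np.isscalar(beta) or getattr(beta, "ndim", 1) == 0:
        return float(out)
    return out


def complete_pair_matrix(
    matrix: BetaMatrix, pairs: Iterable[Pair]
) -> tuple[np.ndarray, np.ndarray, list[Pair]]:
    """AB and OM value arrays (probes x pairs) for the given pairs."""
    pairs = list(pairs)
    ab = matrix.data[[p.ab for p in pairs]].to_numpy(dtype=float)
    om = matrix.data[[p.om for p in pairs]].to_numpy(dtype=float)
    return ab, om, pairs
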