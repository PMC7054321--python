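"""Reading, validation and preprocessing of molecular and clinical tables.

Molecular matrices are delimited text files with samples in rows and features
in columns: the header row carries feature IDs and the first column carries
sample IDs.  Two covariate kinds are supported: continuous expression Z-scores
and 0/1 alteration indicators (mutation present, expression abnormal).
Clinical tables are keyed by ``sample_id`` and carry either a binary outcome
column ``status`` or a survival outcome (``time``, ``event``), plus optional
numeric covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd

MatrixKind = Literal["continuous_zscore", "binary_indicator"]


class DataError(ValueError):
    """Base class for malformed or inconsistent input data."""


class DuplicateIDError(DataError):
    pass


class NonNumericError(DataError):
    pass


class DomainError(DataError):
    """A value violates the declared matrix kind (e.g. 2 in a 0/1 matrix)."""


class EmptyResultError(DataError):
    """A filter removed every feature; downstream fits are impossible."""


class AlignmentError(DataError):
    pass


@dataclass
class MolecularMatrix:
    """Samples x features covariate matrix with IDs.

    Parameters
    ----------
    sample_ids, feature_ids
        Ordered, unique string identifiers.
    values
        ``(n_samples, n_features)`` float array with no missing entries.
    kind
        ``"continuous_zscore"`` or ``"binary_indicator"``.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    kind: MatrixKind

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateIDError("duplicated sample IDs")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise DuplicateIDError("duplicated feature IDs")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise DataError(
                f"value grid {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if np.isnan(self.values).any():
            raise DataError("missing values in molecular matrix")
        if self.kind == "binary_indicator":
            if not np.isin(self.values, (0.0, 1.0)).all():
                bad = self.values[~np.isin(self.values, (0.0, 1.0))][0]
                raise DomainError(
                    f"binary_indicator matrix contains value {bad!r} not in {{0, 1}}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class BinaryOutcome:
    """Binary endpoint y in {0,1} per sample (1 = ``positive_label``)."""

    sample_ids: list[str]
    y: np.ndarray
    positive_label: str = "case"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.y = np.asarray(self.y, dtype=float)
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise DomainError("binary outcome values must be 0 or 1")
        if len(self.y) != len(self.sample_ids):
            raise DataError("outcome length does not match sample IDs")
        if not (0.0 in self.y and 1.0 in self.y):
            raise DataError("both outcome classes must be present")


@dataclass
class SurvivalOutcome:
    """Right-censored survival endpoint: observed time and event indicator.

    ``time`` is min(event time, censoring time); ``event`` is 1 when the event
    was observed and 0 when the subject was censored.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        if len(self.time) != len(self.sample_ids) or len(self.event) != len(self.sample_ids):
            raise DataError("outcome length does not match sample IDs")
        if (self.time < 0).any():
            raise DomainError("survival times must be non-negative")
        if not np.isin(self.event, (0.0, 1.0)).all():
            raise DomainError("event indicator must be 0 or 1")
        if self.event.sum() < 1:
            raise DataError("at least one event is required")


Outcome = Union[BinaryOutcome, SurvivalOutcome]


@dataclass
class AnalysisDataset:
    """Aligned matrix + outcome (+ optional clinical covariates), one row order."""

    X: MolecularMatrix
    outcome: Outcome
    clinical_covariates: Optional[pd.DataFrame] = None
    dropped_sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.X.sample_ids != self.outcome.sample_ids:
            raise AlignmentError("matrix and outcome sample order differ; use align()")
        if self.X.n_samples < 2:
            raise DataError("need at least 2 samples")
        if self.clinical_covariates is not None:
            if list(self.clinical_covariates.index) != self.X.sample_ids:
                raise AlignmentError("clinical covariate rows not aligned to matrix")

    @property
    def n_samples(self) -> int:
        return self.X.n_samples

    @property
    def family(self) -> str:
        return "logistic" if isinstance(self.outcome, BinaryOutcome) else "cox"


def _detect_delimiter(path: Union[str, Path]) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise DataError(
        f"could not auto-detect delimiter of {path}: neither tab nor comma in header; "
        "pass delimiter explicitly"
    )


def read_matrix(
    path: Union[str, Path],
    delimiter: Optional[str] = None,
    kind: MatrixKind = "continuous_zscore",
    drop_missing: bool = False,
) -> MolecularMatrix:
    """Read a samples-x-features delimited matrix.

    First row = feature IDs, first column = sample IDs.  Raises distinct
    errors for duplicated IDs, non-numeric cells and out-of-domain values.
    Missing cells are an error unless ``drop_missing``, which removes any
    feature column containing them (imputation is deliberately not offered).
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise DataError(f"{path}: no feature columns found (wrong delimiter?)")
    if df.index.isnull().any() or df.columns.isnull().any():
        raise DataError(f"{path}: malformed header or missing IDs")
    try:
        values = df.astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise NonNumericError(f"{path}: non-numeric cell ({exc})") from None
    feature_ids = list(df.columns.astype(str))
    if drop_missing and np.isnan(values).any():
        keep = ~np.isnan(values).any(axis=0)
        if not keep.any():
            raise EmptyResultError(f"{path}: every feature has missing values")
        values = values[:, keep]
        feature_ids = [f for f, k in zip(feature_ids, keep) if k]
    return MolecularMatrix(
        sample_ids=list(df.index.astype(str)),
        feature_ids=feature_ids,
        values=values,
        kind=kind,
    )


def write_matrix(M: MolecularMatrix, path: Union[str, Path], delimiter: str = "\t") -> None:
    """Write a matrix in the dialect :func:`read_matrix` reads (round-trips)."""
    df = M.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep=delimiter, float_format="%.17g")
    return None


def read_clinical(
    path: Union[str, Path], delimiter: Optional[str] = None
) -> tuple[Outcome, Optional[pd.DataFrame]]:
    """Read a clinical table: ``sample_id`` plus ``status`` or ``time``+``event``.

    Remaining numeric columns become clinical covariates.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = _detect_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    if "sample_id" not in df.columns:
        raise DataError(f"{path}: clinical table must have a 'sample_id' column")
    ids = list(df["sample_id"].astype(str))
    outcome: Outcome
    if "time" in df.columns and "event" in df.columns:
        outcome = SurvivalOutcome(ids, df["time"].to_numpy(), df["event"].to_numpy())
        extra = df.drop(columns=["sample_id", "time", "event"])
    elif "status" in df.columns:
        outcome = BinaryOutcome(ids, df["status"].to_numpy())
        extra = df.drop(columns=["sample_id", "status"])
    else:
        raise DataError(
            f"{path}: need either a 'status' column or 'time' + 'event' columns"
        )
    clinical = None
    if extra.shape[1] > 0:
        try:
            clinical = extra.astype(float)
        except (TypeError, ValueError) as exc:
            raise NonNumericError(f"{path}: non-numeric clinical covariate ({exc})") from None
        clinical.index = pd.Index(ids)
    return outcome, clinical


def binarize_zscores(M: MolecularMatrix, cutoff: float = 2.0) -> MolecularMatrix:
    """Code |z| > cutoff as abnormal (1), everything else as normal (0).

    The inequality is strict, so z = +/-cutoff itself counts as normal.
    """
    if M.kind != "continuous_zscore":
        raise DataError("binarize_zscores expects a continuous_zscore matrix")
    if not cutoff > 0:
        raise DomainError(f"cutoff must be positive, got {cutoff}")
    out = (np.abs(M.values) > cutoff).astype(float)
    return MolecularMatrix(M.sample_ids, M.feature_ids, out, "binary_indicator")


def prevalence_filter(M: MolecularMatrix, min_fraction: float) -> MolecularMatrix:
    """Keep features altered in at least ``min_fraction`` of samples.

    The study convention: mutations kept at >=1% prevalence, expression
    abnormalities at >=2%.
    """
    if M.kind != "binary_indicator":
        raise DataError("prevalence_filter expects a binary_indicator matrix")
    if not 0 < min_fraction <= 1:
        raise DomainError(f"min_fraction must be in (0, 1], got {min_fraction}")
    frac = M.values.mean(axis=0)
    keep = frac >= min_fraction
    if not keep.any():
        raise EmptyResultError(
            f"no feature reaches prevalence {min_fraction}; nothing left to fit"
        )
    return MolecularMatrix(
        M.sample_ids,
        [f for f, k in zip(M.feature_ids, keep) if k],
        M.values[:, keep],
        "binary_indicator",
    )


def align(
    M: MolecularMatrix,
    outcome: Outcome,
    clinical: Optional[pd.DataFrame] = None,
) -> AnalysisDataset:
    """Restrict matrix, outcome and clinical table to their shared sample IDs.

    Rows are reordered to the matrix's ID order; IDs present in only one
    component are reported via ``dropped_sample_ids``.
    """
    m_ids = set(M.sample_ids)
    o_ids = set(outcome.sample_ids)
    shared = [s for s in M.sample_ids if s in o_ids]
    if clinical is not None:
        c_ids = set(map(str, clinical.index))
        shared = [s for s in shared if s in c_ids]
    if not shared:
        raise AlignmentError("no shared sample IDs between matrix and outcome")
    dropped = sorted((m_ids | o_ids) - set(shared))

    rows = [M.sample_ids.index(s) for s in shared]
    Xa = MolecularMatrix(shared, M.feature_ids, M.values[rows], M.kind)

    o_pos = {s: i for i, s in enumerate(outcome.sample_ids)}
    idx = [o_pos[s] for s in shared]
    if isinstance(outcome, BinaryOutcome):
        oa: Outcome = BinaryOutcome(shared, outcome.y[idx], outcome.positive_label)
    else:
        oa = SurvivalOutcome(shared, outcome.time[idx], outcome.event[idx])

    ca = None
    if clinical is not None:
        ca = clinical.loc[shared].copy()
        if ca.isnull().any().any():
            raise DataError("missing clinical covariate value for a retained sample")
    return AnalysisDataset(Xa, oa, ca, dropped_sample_ids=dropped)
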