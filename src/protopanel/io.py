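"""Tabular input/output and the expression-matrix container.

The pipeline operates on a wide subjects-by-markers intensity table
(raw relative-fluorescence-style units, strictly positive) paired with a
binary case/control label table. All downstream statistics run on
log2-transformed, per-marker standardized values; the pre-standardization
log2 values are retained on the container because fold changes are defined
on that scale while the per-marker z-scoring would erase them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

RAW = "raw"
LOG2 = "log2"
LOG2_STANDARDIZED = "log2_standardized"
_SCALES = (RAW, LOG2, LOG2_STANDARDIZED)


class TableFormatError(ValueError):
    """A malformed expression or label table (parse / schema problem)."""


class AlignmentError(ValueError):
    """Subject ids of the matrix and the labels do not match."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
    if dups:
        raise TableFormatError(f"duplicate {what}: {sorted(set(dups))}")
    return ids


@dataclass
class ExpressionMatrix:
    """Subjects x markers numeric matrix with an explicit scale state.

    Parameters
    ----------
    subject_ids, marker_ids
        Ordered unique identifiers for rows and columns.
    values
        ``(n, p)`` float array on the scale given by ``scale``.
    scale
        One of ``"raw"`` (positive intensities), ``"log2"``, or
        ``"log2_standardized"`` (per-marker z-scores of the log2 values).
    log2_values
        Pre-standardization log2 values, populated by
        :func:`log2_standardize`; used for fold-change computation.
    """

    subject_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray
    scale: str = RAW
    log2_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject_ids = _check_unique(self.subject_ids, "subject ids")
        self.marker_ids = _check_unique(self.marker_ids, "marker ids")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.subject_ids), len(self.marker_ids)):
            raise TableFormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.marker_ids)} markers"
            )
        if self.scale not in _SCALES:
            raise TableFormatError(f"unknown scale {self.scale!r}")
        if np.isnan(self.values).any():
            raise TableFormatError("expression matrix contains missing values")
        if self.scale == RAW and not (self.values > 0).all():
            raise TableFormatError("raw-scale intensities must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def p(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.marker_ids,
        )

    def log2_frame(self) -> pd.DataFrame:
        """Pre-standardization log2 values as a DataFrame."""
        if self.scale == LOG2_STANDARDIZED:
            if self.log2_values is None:
                raise ValueError("standardized matrix lost its log2 values")
            vals = self.log2_values
        elif self.scale == LOG2:
            vals = self.values
        else:
            vals = np.log2(self.values)
        return pd.DataFrame(
            vals, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.marker_ids,
        )


@dataclass
class GroupLabels:
    """Binary delirium status per subject (1 = case, 0 = control)."""

    subject_ids: list[str]
    status: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = _check_unique(self.subject_ids, "subject ids")
        self.status = np.asarray(self.status)
        if self.status.ndim != 1 or len(self.status) != len(self.subject_ids):
            raise TableFormatError("status must be one value per subject")
        if not np.isin(self.status, (0, 1)).all():
            raise TableFormatError("labels must be 0 or 1")
        self.status = self.status.astype(int)

    @property
    def n_case(self) -> int:
        return int(self.status.sum())

    @property
    def n_control(self) -> int:
        return int((1 - self.status).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "status": self.status})


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise TableFormatError(f"{path}: empty file")
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:  # pragma: no cover - sniffed first
        raise TableFormatError(f"{path}: empty file") from exc
    if df.shape[1] < 2:
        raise TableFormatError(f"{path}: expected a subject-id column plus data columns")
    return df


def read_expression(
    path: str | Path,
    labels_path: str | Path,
    missing: str = "error",
) -> tuple[ExpressionMatrix, GroupLabels]:
    """Load a wide expression table and its label table, aligned by subject id.

    The first column of each file is the subject id; the matrix's row order
    wins when aligning. ``missing`` is ``"error"`` (default, fail fast) or
    ``"mean_impute"`` (replace missing cells by the marker mean).
    """
    if missing not in ("error", "mean_impute"):
        raise ValueError(f"unknown missing-value policy {missing!r}")
    df = _read_table(path)
    subject_ids = _check_unique(df.iloc[:, 0].tolist(), "subject ids")
    marker_ids = _check_unique(df.columns[1:].tolist(), "marker ids")

    numeric = np.empty((len(subject_ids), len(marker_ids)), dtype=float)
    for j, col in enumerate(df.columns[1:]):
        # cell-wise float() keeps shortest-repr values bit-exact on reload
        raw = df[col].fillna("")
        for i, cell in enumerate(raw):
            cell = cell.strip()
            if cell == "":
                numeric[i, j] = np.nan
                continue
            try:
                numeric[i, j] = float(cell)
            except ValueError:
                raise TableFormatError(
                    f"{path}: non-numeric cell at subject "
                    f"{subject_ids[i]!r}, marker {col!r}: {cell!r}"
                ) from None
    if np.isnan(numeric).any():
        if missing == "error":
            n_missing = int(np.isnan(numeric).sum())
            raise TableFormatError(f"{path}: {n_missing} missing cell(s)")
        col_means = np.nanmean(numeric, axis=0)
        idx = np.where(np.isnan(numeric))
        numeric[idx] = np.take(col_means, idx[1])

    ldf = _read_table(labels_path)
    label_ids = _check_unique(ldf.iloc[:, 0].tolist(), "subject ids")
    status_raw = pd.to_numeric(ldf.iloc[:, 1], errors="coerce")
    if status_raw.isna().any() or not status_raw.isin((0, 1)).all():
        raise TableFormatError(f"{labels_path}: labels must be 0 or 1")
    by_id = dict(zip(label_ids, status_raw.astype(int)))

    extra = sorted(set(label_ids) - set(subject_ids))
    if extra:
        raise AlignmentError(
            f"label subject(s) absent from the expression matrix: {extra}"
        )
    unlabeled = sorted(set(subject_ids) - set(label_ids))
    if unlabeled:
        raise AlignmentError(f"subject(s) without a label: {unlabeled}")

    matrix = ExpressionMatrix(subject_ids, marker_ids, numeric, scale=RAW)
    labels = GroupLabels(subject_ids, np.array([by_id[s] for s in subject_ids]))
    return matrix, labels


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path)


def write_labels(labels: GroupLabels, path: str | Path) -> None:
    labels.to_frame().to_csv(path, index=False)


def log2_standardize(
    matrix: ExpressionMatrix, zero_variance: str = "error"
) -> ExpressionMatrix:
    """Log2-transform (if raw) then per-marker z-score with the n-1 sample SD.

    Standardization pools cases and controls: one transform feeds every
    downstream analysis. The pre-standardization log2 values are kept on the
    result for fold-change computation. ``zero_variance`` is ``"error"``
    (default) or ``"drop"`` (remove constant markers with a warning).
    """
    if matrix.scale == LOG2_STANDARDIZED:
        raise ValueError("matrix is already log2-standardized (scale guard)")
    if zero_variance not in ("error", "drop"):
        raise ValueError(f"unknown zero-variance policy {zero_variance!r}")
    log2_vals = np.log2(matrix.values) if matrix.scale == RAW else matrix.values.copy()
    sd = log2_vals.std(axis=0, ddof=1)
    constant = sd == 0
    marker_ids = list(matrix.marker_ids)
    if constant.any():
        bad = [m for m, c in zip(marker_ids, constant) if c]
        if zero_variance == "error":
            raise ValueError(f"zero-variance marker(s): {bad}")
        import warnings

        warnings.warn(f"dropping zero-variance marker(s): {bad}", stacklevel=2)
        keep = ~constant
        log2_vals = log2_vals[:, keep]
        sd = sd[keep]
        marker_ids = [m for m, k in zip(marker_ids, keep) if k]
    z = (log2_vals - log2_vals.mean(axis=0)) / sd
    return ExpressionMatrix(
        list(matrix.subject_ids), marker_ids, z,
        scale=LOG2_STANDARDIZED, log2_values=log2_vals,
    )


def write_manifest(path: str | Path, entries: dict) -> None:
    """Write the JSON run manifest (inputs, seed, parameters, version)."""
    from . import __version__

    payload = {"software": "protopanel", "version": __version__, **entries}

    def _default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        raise TypeError(f"cannot serialize {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=_default) + "\n")
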