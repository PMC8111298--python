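"""Readers and writers for the on-disk formats (TSV canonical, CSV accepted)."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import FeatureMatrix

__all__ = [
    "detect_delimiter",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_labels",
    "write_labels",
    "write_square_matrix",
]


def detect_delimiter(path: str | Path, delimiter: str | None = None) -> str:
    """Delimiter from an explicit override or the file extension (.csv -> comma)."""
    if delimiter:
        return delimiter
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_feature_matrix(path: str | Path, delimiter: str | None = None) -> FeatureMatrix:
    """Parse a samples x features table.

    First column: sample IDs; header row: feature IDs; numeric body.
    Ragged rows, non-numeric cells, negatives and duplicate sample IDs are
    rejected with the offending coordinates in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path.name}")
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna().to_numpy())))
        raise ValueError(
            f"missing value (ragged row?) at sample {df.index[row]!r}, "
            f"column {df.columns[col]!r} in {path.name}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for (row, col), cell in np.ndenumerate(df.to_numpy()):
            try:
                float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at sample {df.index[row]!r}, "
                    f"column {df.columns[col]!r} in {path.name}"
                ) from None
        raise
    if np.any(values < 0):
        row, col = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative value {values[row, col]} at sample {df.index[row]!r}, "
            f"column {df.columns[col]!r} in {path.name}"
        )
    return FeatureMatrix(values, tuple(map(str, df.index)), tuple(map(str, df.columns)))


def write_feature_matrix(X: FeatureMatrix, path: str | Path, delimiter: str | None = None) -> None:
    sep = detect_delimiter(path, delimiter)
    df = pd.DataFrame(X.values, index=list(X.sample_ids), columns=list(X.feature_ids))
    df.to_csv(path, sep=sep)


def read_labels(path: str | Path, delimiter: str | None = None) -> pd.Series:
    """Read a two-column (sample_id, label) table into a Series keyed by id."""
    sep = detect_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] != 1:
        raise ValueError(f"label file must have exactly two columns, got {df.shape[1] + 1}")
    return df.iloc[:, 0]


def write_labels(sample_ids, labels, path: str | Path, delimiter: str | None = None) -> None:
    sep = detect_delimiter(path, delimiter)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["sample_id", "cluster"])
        for sid, lab in zip(sample_ids, labels):
            writer.writerow([sid, int(lab)])


def write_square_matrix(M: np.ndarray, sample_ids, path: str | Path, delimiter: str | None = None) -> None:
    """Debug export of W / A / L / V with sample-ID row and column headers."""
    sep = detect_delimiter(path, delimiter)
    ids = list(sample_ids)
    pd.DataFrame(M, index=ids, columns=ids).to_csv(path, sep=sep)
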