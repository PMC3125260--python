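"""Labeled binary profile matrices and train-set normalization.

Drugs are rows; features (chemical substructure bits or side-effect
keywords) are columns.  All downstream analysis consumes the 0/1 matrices
defined here, after per-column centering and scaling fitted on training
rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("fragside")

__all__ = [
    "BinaryProfileMatrix",
    "Normalizer",
    "read_profile_matrix",
    "write_profile_matrix",
    "align_by_ids",
    "fit_normalizer",
    "apply_normalizer",
    "denormalize",
]


@dataclass
class BinaryProfileMatrix:
    """An n x f 0/1 matrix with unique drug row ids and feature column names."""

    row_ids: list[str]
    col_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, f = self.values.shape
        if len(self.row_ids) != n:
            raise ValueError(f"{len(self.row_ids)} row ids for {n} rows")
        if len(self.col_names) != f:
            raise ValueError(f"{len(self.col_names)} column names for {f} columns")
        if len(set(self.row_ids)) != n:
            raise ValueError("duplicate row ids")
        if len(set(self.col_names)) != f:
            raise ValueError("duplicate column names")
        if not np.isin(self.values, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.values, (0, 1)))[0]
            raise ValueError(
                f"non-binary entry at row {self.row_ids[bad[0]]!r}, "
                f"column {self.col_names[bad[1]]!r}"
            )
        self.values = self.values.astype(np.int8)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def f(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_names)


@dataclass
class Normalizer:
    """Per-column mean/sd fitted on training rows (population sd, divisor n).

    Columns constant on the training rows are flagged; they are centered and
    divided by a substituted sd of 1, so their normalized values are all zero
    and the feature is inert downstream.
    """

    means: np.ndarray
    sds: np.ndarray
    zero_var_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.means.shape != self.sds.shape:
            raise ValueError("means and sds must have equal length")
        if (self.sds < 0).any():
            raise ValueError("negative standard deviation")
        if self.zero_var_mask is None:
            self.zero_var_mask = self.sds == 0
        self.zero_var_mask = np.asarray(self.zero_var_mask, dtype=bool)


def read_profile_matrix(path: str | Path, delimiter: str = "\t") -> BinaryProfileMatrix:
    """Read a labeled 0/1 matrix: header of feature names, first column drug ids."""
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no rows")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate drug id {dup!r}")
    values = np.empty(df.shape, dtype=np.int8)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        ok = np.isin(raw, ("0", "1"))
        if not ok.all():
            i = int(np.argmin(ok))
            raise ValueError(
                f"{path}: non-binary value {raw[i]!r} at row {df.index[i]!r}, "
                f"column {col!r}"
            )
        values[:, j] = raw == "1"
    return BinaryProfileMatrix(
        row_ids=[str(i) for i in df.index],
        col_names=[str(c) for c in df.columns],
        values=values,
    )


def write_profile_matrix(
    M: BinaryProfileMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    df = M.to_frame()
    df.index.name = "id"
    df.to_csv(path, sep=delimiter)


def align_by_ids(
    X: BinaryProfileMatrix, Y: BinaryProfileMatrix
) -> tuple[BinaryProfileMatrix, BinaryProfileMatrix]:
    """Restrict both matrices to shared drug ids, in lexicographic order."""
    common = sorted(set(X.row_ids) & set(Y.row_ids))
    if not common:
        raise ValueError("no shared drug ids between the two matrices")
    for name, M in (("X", X), ("Y", Y)):
        dropped = set(M.row_ids) - set(common)
        if dropped:
            logger.info("align_by_ids: dropping %d %s-only ids", len(dropped), name)
    xi = {r: i for i, r in enumerate(X.row_ids)}
    yi = {r: i for i, r in enumerate(Y.row_ids)}
    Xa = BinaryProfileMatrix(common, X.col_names, X.values[[xi[r] for r in common]])
    Ya = BinaryProfileMatrix(common, Y.col_names, Y.values[[yi[r] for r in common]])
    return Xa, Ya


def fit_normalizer(M: BinaryProfileMatrix | np.ndarray) -> Normalizer:
    """Column means and population standard deviations (divisor n)."""
    V = M.values if isinstance(M, BinaryProfileMatrix) else np.asarray(M)
    if V.shape[0] < 2:
        raise ValueError("need at least 2 rows to fit a normalizer")
    means = V.mean(axis=0, dtype=float)
    sds = V.std(axis=0, ddof=0)
    return Normalizer(means=means, sds=sds, zero_var_mask=sds == 0)


def _coerce_2d(V) -> tuple[np.ndarray, bool]:
    A = np.asarray(V, dtype=float)
    if A.ndim == 1:
        return A[None, :], True
    return A, False


def apply_normalizer(norm: Normalizer, M) -> np.ndarray:
    """Center and scale columns; zero-variance columns come out all zero."""
    V, squeeze = _coerce_2d(M.values if isinstance(M, BinaryProfileMatrix) else M)
    if V.shape[1] != norm.means.shape[0]:
        raise ValueError(
            f"matrix has {V.shape[1]} columns, normalizer expects {norm.means.shape[0]}"
        )
    sds = np.where(norm.zero_var_mask, 1.0, norm.sds)
    out = (V - norm.means) / sds
    out[:, norm.zero_var_mask] = 0.0
    return out[0] if squeeze else out


def denormalize(norm: Normalizer, V) -> np.ndarray:
    """Invert apply_normalizer: V*sd + mean (sd substituted with 1 where constant)."""
    A, squeeze = _coerce_2d(V)
    if A.shape[1] != norm.means.shape[0]:
        raise ValueError(
            f"matrix has {A.shape[1]} columns, normalizer expects {norm.means.shape[0]}"
        )
    sds = np.where(norm.zero_var_mask, 1.0, norm.sds)
    out = A * sds + norm.means
    return out[0] if squeeze else out
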