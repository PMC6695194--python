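"""Core data containers for chemogenomic bioactivity matrices.

A bioactivity matrix holds quantitative assay readouts (typically percent
inhibition) for a panel of targets (rows) screened against a compound
library (columns).  Everything downstream — informer-set selection,
compound ranking, evaluation — consumes these containers.

Two derived views matter throughout:

* the *binary* activity matrix, obtained by calling a compound active on a
  target when its readout is at least two sample standard deviations above
  that target's row mean, and
* the *column-scaled* matrix, where each compound's column is mapped
  linearly onto [0, 1] so that clustering is not dominated by compounds
  with wide raw dynamic range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BioactivityMatrix",
    "BinaryActivityMatrix",
    "ColumnScaler",
    "InformerSet",
    "TargetPartition",
    "read_bioactivity_csv",
    "write_bioactivity_csv",
    "binarize_matrix",
    "binarize_row",
    "scale_columns_unit_interval",
    "remove_target",
]


class MatrixValidationError(ValueError):
    """Raised when a bioactivity matrix violates its structural invariants."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MatrixValidationError(f"duplicate {what} ID: {x!r}")
        seen.add(x)
    return ids


@dataclass
class BioactivityMatrix:
    """Quantitative targets-by-compounds activity table.

    Parameters
    ----------
    values : ndarray of shape (m, n)
        Real-valued readouts; all entries must be finite.
    target_ids, compound_ids : sequences of str
        Unique row and column identifiers, kept in order.
    """

    values: np.ndarray
    target_ids: list[str]
    compound_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D array")
        self.target_ids = _check_unique(self.target_ids, "target")
        self.compound_ids = _check_unique(self.compound_ids, "compound")
        m, n = self.values.shape
        if m != len(self.target_ids) or n != len(self.compound_ids):
            raise MatrixValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.target_ids)} targets x {len(self.compound_ids)} compounds"
            )
        if m < 1 or n < 1:
            raise MatrixValidationError("matrix must be non-empty")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise MatrixValidationError(
                f"non-finite entry at target {self.target_ids[bad[0]]!r}, "
                f"compound {self.compound_ids[bad[1]]!r}"
            )

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def target_index(self, target_id: str) -> int:
        try:
            return self.target_ids.index(str(target_id))
        except ValueError:
            raise KeyError(f"unknown target ID: {target_id!r}") from None

    def compound_index(self, compound_id: str) -> int:
        try:
            return self.compound_ids.index(str(compound_id))
        except ValueError:
            raise KeyError(f"unknown compound ID: {compound_id!r}") from None

    def compound_indices(self, compound_ids: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        try:
            return np.array([pos[str(c)] for c in compound_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown compound ID: {exc.args[0]!r}") from None

    def row(self, target_id: str) -> np.ndarray:
        return self.values[self.target_index(target_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.target_ids, columns=self.compound_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BioactivityMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            target_ids=[str(i) for i in frame.index],
            compound_ids=[str(c) for c in frame.columns],
        )


@dataclass
class BinaryActivityMatrix:
    """0/1 activity calls aligned to a parent :class:`BioactivityMatrix`.

    ``values[i, j] == 1`` iff the raw readout met or exceeded the
    per-target threshold ``thresholds[i]`` (row mean + 2 row sample SD).
    """

    values: np.ndarray
    thresholds: np.ndarray
    target_ids: list[str]
    compound_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if not np.isin(self.values, (0, 1)).all():
            raise MatrixValidationError("binary matrix entries must be 0 or 1")
        if self.values.shape[0] != self.thresholds.shape[0]:
            raise MatrixValidationError("one threshold per target required")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    def compound_indices(self, compound_ids: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        return np.array([pos[str(c)] for c in compound_ids], dtype=int)

    def active_fraction(self) -> np.ndarray:
        """Per-target fraction of active compounds (the 'hit rate')."""
        return self.values.mean(axis=1)


@dataclass
class InformerSet:
    """Ordered informer compound selection plus method provenance."""

    compound_ids: list[str]
    method: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.compound_ids = _check_unique(self.compound_ids, "informer compound")

    def __len__(self) -> int:
        return len(self.compound_ids)

    def __iter__(self):
        return iter(self.compound_ids)


@dataclass
class TargetPartition:
    """Assignment of targets to K clusters with the k-means objective value."""

    K: int
    labels: dict[str, int]
    objective: float = float("nan")

    def __post_init__(self) -> None:
        blocks = set(self.labels.values())
        if not blocks:
            raise MatrixValidationError("partition must label at least one target")
        if blocks != set(range(self.K)):
            raise MatrixValidationError(
                f"block labels must be 0..{self.K - 1} with every block non-empty"
            )

    def label_array(self, target_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[str(t)] for t in target_ids], dtype=int)


# ---------------------------------------------------------------------------
# I/O


def read_bioactivity_csv(path, targets_as_rows: bool = True) -> BioactivityMatrix:
    """Read a bioactivity matrix from CSV.

    The canonical layout has one header row of compound IDs and the first
    column holding target IDs.  ``targets_as_rows=False`` accepts the
    transposed layout (compounds on rows) and transposes on load.
    """
    try:
        # pandas mangles duplicate headers (C1 -> C1.1), so check them raw
        header = pd.read_csv(path, header=None, nrows=1).iloc[0, 1:].astype(str)
        if header.duplicated().any():
            dup = header[header.duplicated()].iloc[0]
            raise MatrixValidationError(f"duplicate column ID in {path!s}: {dup!r}")
        frame = pd.read_csv(path, index_col=0, header=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise MatrixValidationError(f"malformed CSV {path!s}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise MatrixValidationError(f"duplicate row ID in {path!s}: {dup!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        row, col = next(
            (r, c) for r, c in zip(*np.where(numeric.isna().to_numpy()))
        )
        raise MatrixValidationError(
            f"missing or non-numeric cell in {path!s} at row "
            f"{frame.index[row]!r}, column {frame.columns[col]!r}"
        )
    if not targets_as_rows:
        numeric = numeric.T
    return BioactivityMatrix.from_frame(numeric)


def write_bioactivity_csv(X: BioactivityMatrix, path) -> None:
    X.to_frame().to_csv(path, index_label="target_id")


# ---------------------------------------------------------------------------
# Transforms


def binarize_row(row: np.ndarray) -> tuple[np.ndarray, float]:
    """Threshold one activity vector at its mean + 2 sample SD."""
    row = np.asarray(row, dtype=float)
    if row.size < 2:
        raise MatrixValidationError("need at least 2 entries to binarize a row")
    threshold = float(row.mean() + 2.0 * row.std(ddof=1))
    return (row >= threshold).astype(np.int8), threshold


def binarize_matrix(X: BioactivityMatrix) -> BinaryActivityMatrix:
    """Call actives per target at the row mean + 2 sample SD threshold.

    A constant row has SD 0, so every entry ties the threshold and is
    labeled active; this pathological case is kept but warned about.
    """
    if X.n < 2:
        raise MatrixValidationError("binarization needs at least 2 compounds")
    mu = X.values.mean(axis=1)
    sd = X.values.std(axis=1, ddof=1)
    constant = sd == 0.0
    if constant.any():
        bad = [X.target_ids[i] for i in np.where(constant)[0]]
        warnings.warn(
            f"constant activity row(s) {bad}: all compounds labeled active",
            UserWarning,
            stacklevel=2,
        )
    thresholds = mu + 2.0 * sd
    values = (X.values >= thresholds[:, None]).astype(np.int8)
    return BinaryActivityMatrix(
        values=values,
        thresholds=thresholds,
        target_ids=list(X.target_ids),
        compound_ids=list(X.compound_ids),
    )


@dataclass
class ColumnScaler:
    """Per-compound min/max learned on a training matrix.

    New-target readouts on informer compounds are placed on the same
    [0, 1] scale with these parameters, clipping values outside the
    training range.  Constant columns map to 0 (no signal variation).
    """

    col_min: np.ndarray
    col_max: np.ndarray
    compound_ids: list[str]

    def transform_columns(self, values: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (values - self.col_min) / span
        out = np.where(span == 0.0, 0.0, out)
        return np.clip(out, 0.0, 1.0)

    def transform_assays(self, assays: Mapping[str, float]) -> dict[str, float]:
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        out: dict[str, float] = {}
        for cid, val in assays.items():
            j = pos.get(str(cid))
            if j is None:
                raise KeyError(f"compound {cid!r} not in training matrix")
            lo, hi = self.col_min[j], self.col_max[j]
            if hi == lo:
                out[str(cid)] = 0.0
            else:
                out[str(cid)] = float(np.clip((val - lo) / (hi - lo), 0.0, 1.0))
        return out


def scale_columns_unit_interval(
    X: BioactivityMatrix,
) -> tuple[BioactivityMatrix, ColumnScaler]:
    """Map each compound column linearly onto [0, 1].

    Returns the scaled matrix and the fitted :class:`ColumnScaler` so new
    intermediate data can be placed on the same scale.  Idempotent on
    already-[0,1] columns with endpoints 0 and 1.
    """
    lo = X.values.min(axis=0)
    hi = X.values.max(axis=0)
    constant = hi == lo
    if constant.any():
        bad = [X.compound_ids[j] for j in np.where(constant)[0]]
        warnings.warn(
            f"constant compound column(s) {bad} scaled to 0", UserWarning, stacklevel=2
        )
    scaler = ColumnScaler(col_min=lo, col_max=hi, compound_ids=list(X.compound_ids))
    scaled = BioactivityMatrix(
        values=scaler.transform_columns(X.values),
        target_ids=list(X.target_ids),
        compound_ids=list(X.compound_ids),
    )
    return scaled, scaler


def remove_target(X: BioactivityMatrix, target_id: str) -> BioactivityMatrix:
    """Drop one target row, preserving the order of the rest."""
    i = X.target_index(target_id)
    if X.m <= 1:
        raise MatrixValidationError("cannot remove the last remaining target")
    keep = [k for k in range(X.m) if k != i]
    return BioactivityMatrix(
        values=X.values[keep],
        target_ids=[X.target_ids[k] for k in keep],
        compound_ids=list(X.compound_ids),
    )
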