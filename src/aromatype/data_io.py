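"""Feature tables, CSV round-tripping and stratified sample splitting.

The central container is :class:`FeatureTable`: a samples x features matrix of
continuous chemical contents (mg g^-1 for primitive indices, derived units for
composites) with optional integer aroma-type labels in {0, 1, 2}
(0 = fresh-sweet, 1 = honey-sweet, 2 = mellow-sweet).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VALID_LABELS = (0, 1, 2)
N_CLASSES = 3
DEFAULT_LABEL_COLUMN = "aroma_type"
_ID_COLUMN = "sample_id"


@dataclass
class FeatureTable:
    """Samples x features table of continuous chemical contents.

    Parameters
    ----------
    sample_ids
        Unique identifiers, one per row.
    feature_names
        Ordered, unique column names.
    values
        Float matrix of shape ``(len(sample_ids), len(feature_names))`` with
        no missing values.
    labels
        Optional per-sample aroma-type code in {0, 1, 2}.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids):
            raise ValueError(
                f"row count {n} does not match {len(self.sample_ids)} sample ids"
            )
        if p != len(self.feature_names):
            raise ValueError(
                f"column count {p} does not match {len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"feature {self.feature_names[j]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise ValueError("labels must be one integer per sample")
            bad = set(np.unique(self.labels)) - set(VALID_LABELS)
            if bad:
                raise ValueError(f"unknown label value(s) {sorted(bad)}; expected 0/1/2")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def select_features(self, names: Sequence[str]) -> "FeatureTable":
        """Restrict to the given feature columns (in the given order)."""
        idx = [self.feature_names.index(n) for n in names]
        return replace(
            self,
            feature_names=list(names),
            values=self.values[:, idx].copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def take(self, indices: Sequence[int]) -> "FeatureTable":
        """Row subset by positional indices."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[idx].copy(),
            labels=None if self.labels is None else self.labels[idx].copy(),
        )

    def class_indices(self, label: int) -> np.ndarray:
        if self.labels is None:
            raise ValueError("table has no labels")
        return np.flatnonzero(self.labels == label)

    def to_dataframe(self, label_column: str = DEFAULT_LABEL_COLUMN) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, _ID_COLUMN, self.sample_ids)
        if self.labels is not None:
            df[label_column] = self.labels
        return df


def read_feature_table(
    path: str | Path, label_column: str | None = None
) -> FeatureTable:
    """Read a feature table from CSV.

    The label column (when named) must contain only 0/1/2.  A ``sample_id``
    column, when present, supplies identifiers; otherwise row indices are used.
    Any cell that does not parse as a finite number is an error naming the
    offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip parsing: full-precision floats survive a write/read cycle
    df = pd.read_csv(path, float_precision="round_trip", dtype={_ID_COLUMN: str})
    if df.columns.size == 0:
        raise ValueError(f"{path}: no header row")
    if label_column is not None and label_column not in df.columns:
        raise ValueError(f"{path}: label column {label_column!r} not found")

    if _ID_COLUMN in df.columns:
        sample_ids = [str(s) for s in df.pop(_ID_COLUMN)]
    else:
        sample_ids = [str(i) for i in range(len(df))]

    labels = None
    if label_column is not None:
        raw = df.pop(label_column)
        _check_numeric(raw, label_column, path)
        labels = raw.to_numpy(dtype=float)
        if not np.all(labels == np.round(labels)) or not np.all(
            np.isin(labels.astype(int), VALID_LABELS)
        ):
            bad = labels[~np.isin(labels, VALID_LABELS)][0]
            raise ValueError(f"{path}: unknown label value {bad!r} (expected 0/1/2)")
        labels = labels.astype(int)

    for col in df.columns:
        _check_numeric(df[col], col, path)
    values = df.to_numpy(dtype=float)
    return FeatureTable(sample_ids, list(df.columns), values, labels)


def _check_numeric(series: pd.Series, col: str, path: Path) -> None:
    """Raise, naming the first offending cell, unless every value is finite."""
    if len(series) == 0:
        return
    if series.dtype.kind in "if":
        arr = series.to_numpy(dtype=float)
        if np.all(np.isfinite(arr)):
            return
        bad = ~np.isfinite(arr)
    else:
        bad = np.ones(len(series), dtype=bool)
        for i, cell in enumerate(series):
            try:
                bad[i] = not np.isfinite(float(cell))
            except (TypeError, ValueError):
                bad[i] = True
    row = int(np.flatnonzero(bad)[0])
    raise ValueError(
        f"{path}: non-numeric or missing value {series.iloc[row]!r} "
        f"at row {row}, column {col!r}"
    )


def write_feature_table(
    table: FeatureTable, path: str | Path, label_column: str = DEFAULT_LABEL_COLUMN
) -> None:
    """Write a feature table to CSV (UTF-8, ``.`` decimal, header mandatory).

    Floats are serialized at full precision (``repr`` round-trip); the label
    column is last when present.
    """
    df = table.to_dataframe(label_column=label_column)
    df.to_csv(path, index=False, float_format=None)


def _test_counts_per_class(
    class_sizes: Sequence[int], test_fraction: float
) -> list[int]:
    """Largest-remainder apportionment of round(N * fraction) test seats.

    Each class gets floor(n_i * fraction); remaining seats go to the classes
    with the largest fractional remainders, ties broken by smaller class index.
    """
    sizes = np.asarray(class_sizes, dtype=int)
    total_test = int(np.floor(sizes.sum() * test_fraction + 0.5))
    exact = sizes * test_fraction
    floors = np.floor(exact).astype(int)
    remainders = exact - floors
    seats = total_test - int(floors.sum())
    order = sorted(range(len(sizes)), key=lambda c: (-remainders[c], c))
    counts = floors.copy()
    for c in order[:seats]:
        counts[c] += 1
    return counts.tolist()


def stratified_split(
    table: FeatureTable, test_fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Stratified train/test partition by aroma type.

    Per-class test counts follow largest-remainder apportionment so the test
    set holds round(N * test_fraction) samples with class proportions within
    one sample of the global ones; within-class membership is randomized by
    ``seed``.  With class sizes (411, 151, 57) and fraction 0.2 this yields
    test counts (82, 30, 12).
    """
    if table.labels is None:
        raise ValueError("stratified_split requires labels")
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must be in [0, 1)")
    present = [c for c in VALID_LABELS if np.any(table.labels == c)]
    if test_fraction > 0 and len(present) == 0:
        raise ValueError("no samples to split")
    class_sizes = [int(np.sum(table.labels == c)) for c in present]
    if test_fraction > 0 and any(s == 0 for s in class_sizes):
        raise ValueError("every class must have at least one sample")
    counts = _test_counts_per_class(class_sizes, test_fraction)

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c, k in zip(present, counts):
        members = np.flatnonzero(table.labels == c)
        perm = rng.permutation(members)
        test_idx.extend(perm[:k].tolist())
    test_mask = np.zeros(table.n_samples, dtype=bool)
    test_mask[test_idx] = True
    test = table.take(np.flatnonzero(test_mask))
    train = table.take(np.flatnonzero(~test_mask))
    return train, test


def stratified_kfold(
    labels: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold index pairs (train_idx, test_idx).

    Each class's (shuffled) members are dealt into ``n_folds`` nearly equal
    chunks, keeping fold label proportions within one sample of global.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    fold_members: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if len(members) < n_folds:
            raise ValueError(
                f"class {c} has {len(members)} samples; needs >= {n_folds} for "
                f"{n_folds}-fold stratification"
            )
        perm = rng.permutation(members)
        for f, chunk in enumerate(np.array_split(perm, n_folds)):
            fold_members[f].extend(chunk.tolist())
    folds = []
    all_idx = np.arange(len(labels))
    for f in range(n_folds):
        test_idx = np.sort(np.asarray(fold_members[f], dtype=int))
        train_idx = np.setdiff1d(all_idx, test_idx)
        folds.append((train_idx, test_idx))
    return folds
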