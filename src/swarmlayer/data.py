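"""Feature tables, CSV I/O and the stratified 70:15:15 split.

A :class:`FeatureTable` is the currency of the pipeline: an n x d matrix
of per-image embedding features plus binary labels (0 = Normal,
1 = OSCC).  The split counts use the floor convention: per class,
floor(val_frac*n) validation rows, floor(test_frac*n) test rows, and the
remainder for training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SplitSpec",
    "DatasetSplits",
    "stratified_split",
    "read_feature_table",
    "write_feature_table",
]


@dataclass
class FeatureTable:
    """n x d feature matrix with binary labels and column names."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels, dtype=int)
        n, d = self.features.shape
        if d < 1:
            raise ValueError("need at least one feature column")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} rows")
        if n and not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain missing or non-finite values")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(d)]
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must equal feature count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def take(self, indices) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(self.features[idx], self.labels[idx], list(self.feature_names))


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (default 70:15:15) and shuffle seed."""

    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.train_frac, self.val_frac, self.test_frac):
            if not 0.0 < f < 1.0:
                raise ValueError("all fractions must lie in (0, 1)")
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class DatasetSplits:
    train: FeatureTable
    val: FeatureTable
    test: FeatureTable


def split_counts(n_class: int, spec: SplitSpec) -> tuple:
    """Per-class (train, val, test) counts under the floor convention."""
    n_val = math.floor(spec.val_frac * n_class)
    n_test = math.floor(spec.test_frac * n_class)
    return n_class - n_val - n_test, n_val, n_test


def stratified_split(table: FeatureTable, spec: SplitSpec) -> DatasetSplits:
    """Shuffle within each class and partition per the floor convention.

    Every input row lands in exactly one part; per-class proportions are
    preserved up to the integer rounding of the counts.
    """
    rng = np.random.default_rng(spec.seed)
    train_idx, val_idx, test_idx = [], [], []
    for label in sorted(np.unique(table.labels)):
        cls = np.flatnonzero(table.labels == label)
        if len(cls) < 3:
            raise ValueError(
                f"class {label} has only {len(cls)} samples; need at least 3"
            )
        perm = rng.permutation(cls)
        n_train, n_val, n_test = split_counts(len(cls), spec)
        train_idx.append(perm[:n_train])
        val_idx.append(perm[n_train : n_train + n_val])
        test_idx.append(perm[n_train + n_val :])
    return DatasetSplits(
        train=table.take(np.concatenate(train_idx)),
        val=table.take(np.concatenate(val_idx)),
        test=table.take(np.concatenate(test_idx)),
    )


def write_feature_table(table: FeatureTable, path, format: str = "csv"):
    """Write ``f0,...,f{d-1},label`` CSV with full-precision decimals."""
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    df = pd.DataFrame(table.features, columns=table.feature_names)
    df["label"] = table.labels
    # repr-precision floats round-trip exactly
    df.to_csv(path, index=False, float_format=None)
    return path


def read_feature_table(path, format: str = "csv") -> FeatureTable:
    """Read a CSV written by :func:`write_feature_table` (or compatible)."""
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty feature-table file") from exc
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing required 'label' column")
    feature_cols = [c for c in df.columns if c != "label"]
    if not feature_cols:
        raise ValueError(f"{path}: no feature columns")
    for col in feature_cols + ["label"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {df[col][row]!r} at row {row}, "
                f"column {col!r}"
            )
        if df[col].isna().any():
            row = int(df[col].isna().idxmax())
            raise ValueError(f"{path}: missing value at row {row}, column {col!r}")
        df[col] = coerced
    return FeatureTable(
        features=df[feature_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        feature_names=feature_cols,
    )
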