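"""Participant-by-index feature tables: CSV I/O, label coding, standardization.

The universal input of the package is a numeric table with one row per
participant, one column per clinical index, and a binary class label
(1 = positive / "drivable", 2 = negative / "undrivable").  All model code
assumes standardized columns (mean 0, SD 1); standardization parameters are
kept so that held-out rows can be transformed with training-fold statistics
without leaking information.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


@dataclass
class FeatureTable:
    """N participants x P indices with binary labels in {1, 2}.

    Parameters
    ----------
    values
        ``(N, P)`` float array of index values.
    labels
        ``(N,)`` int array with entries in ``{1, 2}``; 1 is the positive
        (drivable) class.
    index_names
        Unique column names, length ``P``.
    standardized
        Whether columns have been transformed to mean 0 / SD 1.
    standardization_params
        ``(means, sds)`` pair of length-``P`` arrays, present after
        standardization (or when the table was produced by
        :func:`apply_standardization`).
    """

    values: np.ndarray
    labels: np.ndarray
    index_names: list[str]
    standardized: bool = False
    standardization_params: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of rows")
        if not set(np.unique(self.labels)) <= {1, 2}:
            raise ValueError("labels must be coded in {1, 2}")
        if len(self.index_names) != p:
            raise ValueError("index_names length must match number of columns")
        if len(set(self.index_names)) != p:
            raise ValueError("index names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains missing/non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_indices(self) -> int:
        return self.values.shape[1]

    def onehot_targets(self) -> np.ndarray:
        """One-of-C target matrix ``(N, 2)``; column 0 is class 1."""
        t = np.zeros((self.n_samples, 2))
        t[np.arange(self.n_samples), self.labels - 1] = 1.0
        return t

    def subset_rows(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.values[rows],
            self.labels[rows],
            list(self.index_names),
            self.standardized,
            self.standardization_params,
        )

    def subset_columns(self, names: Sequence[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.index_names]
        if missing:
            raise KeyError(f"unknown index names: {missing}")
        cols = [self.index_names.index(n) for n in names]
        params = None
        if self.standardization_params is not None:
            means, sds = self.standardization_params
            params = (means[cols], sds[cols])
        return FeatureTable(
            self.values[:, cols], self.labels, list(names), self.standardized, params
        )


def read_feature_table(
    path: str | Path, label_column: str, positive_label: str | None = None
) -> FeatureTable:
    """Read a CSV file into a :class:`FeatureTable`.

    The file must have a header row; ``label_column`` must contain exactly two
    distinct values.  ``positive_label`` names the value mapped to class 1
    (defaults to the lexicographically smaller one, so the mapping is
    deterministic either way).  Column order of the indices is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise KeyError(f"label column {label_column!r} not found")
    raw_labels = df[label_column].astype(str)
    levels = sorted(raw_labels.unique())
    if len(levels) != 2:
        raise ValueError(
            f"label column must have exactly 2 distinct values, got {levels}"
        )
    if positive_label is None:
        positive_label = levels[0]
    elif str(positive_label) not in levels:
        raise ValueError(f"positive label {positive_label!r} not among {levels}")
    labels = np.where(raw_labels == str(positive_label), 1, 2)

    features = df.drop(columns=[label_column])
    index_names = list(features.columns)
    if len(set(index_names)) != len(index_names):
        raise ValueError("duplicate index names in header")
    try:
        values = features.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in feature columns: {exc}") from exc
    if np.isnan(values).any():
        bad = [index_names[j] for j in np.unique(np.where(np.isnan(values))[1])]
        raise ValueError(f"missing values in columns {bad}; imputation is not supported")
    return FeatureTable(values, labels, index_names)


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    label_column: str = "label",
    label_names: tuple[str, str] = ("drivable", "undrivable"),
) -> None:
    """Write a table to CSV (values bit-exactly round-trippable via repr)."""
    df = pd.DataFrame(table.values, columns=table.index_names)
    df[label_column] = np.where(table.labels == 1, label_names[0], label_names[1])
    df.to_csv(path, index=False, float_format="%.17g")


def _column_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = values.mean(axis=0)
    # sample SD (n-1 denominator)
    sds = values.std(axis=0, ddof=1)
    return means, sds


def standardize(table: FeatureTable, on_constant: str = "error") -> FeatureTable:
    """Transform each column to (x - mean) / sd using its own sample statistics.

    Parameters are stored on the result for reuse on held-out rows.
    ``on_constant`` controls zero-SD columns: ``"error"`` raises naming the
    column; ``"zero"`` centers the column and substitutes SD 1, leaving an
    all-zero (uninformative) column — used by cross-validation paths where a
    near-degenerate binary index may realize constant within a training fold.
    """
    if table.standardized:
        raise ValueError("table is already standardized")
    means, sds = _column_stats(table.values)
    zero = sds == 0
    if zero.any():
        if on_constant == "error":
            bad = [table.index_names[j] for j in np.where(zero)[0]]
            raise ValueError(f"constant column(s) cannot be standardized: {bad}")
        elif on_constant == "zero":
            sds = np.where(zero, 1.0, sds)
        else:
            raise ValueError(f"unknown on_constant policy {on_constant!r}")
    values = (table.values - means) / sds
    return FeatureTable(
        values, table.labels, list(table.index_names), True, (means, sds)
    )


def apply_standardization(
    table: FeatureTable, params: tuple[np.ndarray, np.ndarray]
) -> FeatureTable:
    """Transform rows with previously stored (means, sds) — e.g. training-fold
    parameters applied to a validation fold."""
    means, sds = np.asarray(params[0], float), np.asarray(params[1], float)
    if means.shape != (table.n_indices,) or sds.shape != (table.n_indices,):
        raise ValueError("standardization params length must equal P")
    values = (table.values - means) / sds
    return FeatureTable(
        values, table.labels, list(table.index_names), True, (means, sds)
    )


def invert_standardization(table: FeatureTable) -> FeatureTable:
    """Undo a stored standardization (testing / export convenience)."""
    if not table.standardized or table.standardization_params is None:
        raise ValueError("table has no standardization to invert")
    means, sds = table.standardization_params
    return FeatureTable(
        table.values * sds + means, table.labels, list(table.index_names), False, None
    )


@dataclass
class AnalysisConfig:
    """Run configuration for training, tuning and cross-validation.

    Defaults follow the study protocol: SGD with learning rate 0.01, batch
    size 50, at most 10,000 epochs, early stopping once the epoch loss fails
    to improve by more than 1e-4 for more than 5 consecutive epochs, and
    11-fold cross-validation.  ``lam`` is the L1 coefficient of the reduction
    layer — a number, or ``"tpe"`` to tune it with the tree-structured Parzen
    estimator over a log-uniform range.
    """

    learning_rate: float = 0.01
    batch_size: int = 50
    max_epochs: int = 10000
    early_stop_min_delta: float = 1e-4
    early_stop_patience: int = 5
    lam: float | str = "tpe"
    n_components: int = 1
    n_folds: int = 11
    seed: int = 0
    feature_subset: list[str] | None = None
    # TPE search settings (study's exact settings unpublished; see docs/methods.md)
    tpe_low: float = 1e-5
    tpe_high: float = 10.0
    tpe_trials: int = 100
    tpe_inner_folds: int = 5
    tpe_scope: str = "global"  # "global" | "per_fold" (pipeline-level switch)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate and batch_size must be positive")
        if self.max_epochs < 0 or self.early_stop_patience < 0:
            raise ValueError("max_epochs and patience must be non-negative")
        if self.n_components < 1 or self.n_folds < 2:
            raise ValueError("n_components >= 1 and n_folds >= 2 required")
        if isinstance(self.lam, str):
            if self.lam != "tpe":
                raise ValueError("lam must be a non-negative number or 'tpe'")
        elif self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.tpe_scope not in ("global", "per_fold"):
            raise ValueError("tpe_scope must be 'global' or 'per_fold'")

    def replace(self, **kwargs) -> "AnalysisConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
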