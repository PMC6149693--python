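"""Labeled expression matrices: I/O, standardization, CV folds, synthesis.

The universal input is a sample-by-feature numeric matrix with one
categorical class label per sample, read from delimited text (CSV/TSV).
Microarray exports frequently store features in rows, so both orientations
are supported.  A synthetic generator emulates the high-dimension /
small-sample regime of public expression benchmarks: a small planted set of
class-informative features, correlated redundant copies of them, and a
large irrelevant remainder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "StandardizationParams",
    "SyntheticSpec",
    "read_matrix",
    "write_matrix",
    "standardize",
    "stratified_folds",
    "generate_synthetic",
]


@dataclass
class ExpressionDataset:
    """A labeled sample-by-feature matrix.

    Invariants (checked at construction): matrix is 2-D with one label per
    row, no missing values, at least 2 classes each with >= 2 samples, and
    unique feature names.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x features)")
        n, p = self.matrix.shape
        if self.labels.shape[0] != n:
            raise ValueError(
                f"label count {self.labels.shape[0]} does not match {n} samples"
            )
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal n_features")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must equal n_samples")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix contains missing or non-finite values")
        classes, counts = np.unique(self.labels, return_counts=True)
        if classes.size < 2:
            raise ValueError("need at least 2 distinct class labels")
        if counts.min() < 2:
            small = classes[counts.argmin()]
            raise ValueError(
                f"class {small!r} has fewer than 2 samples; stratified folds impossible"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset_features(self, indices: list[int] | np.ndarray) -> "ExpressionDataset":
        """New dataset restricted to the given feature columns (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            self.matrix[:, idx],
            self.labels.copy(),
            [self.feature_names[i] for i in idx],
            list(self.sample_ids),
        )


@dataclass
class StandardizationParams:
    """Per-feature location/scale of a z-scoring transform.

    Constant features record std 1 so the transform stays total; applying
    it maps them to zero.
    """

    means: np.ndarray
    stds: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        if self.means.shape != self.stds.shape or self.means.ndim != 1:
            raise ValueError("means and stds must be 1-D vectors of equal length")
        if not np.all(self.stds > 0):
            raise ValueError("stds must be strictly positive")

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.means) / self.stds

    def inverse_transform(self, matrix: np.ndarray) -> np.ndarray:
        return np.asarray(matrix, dtype=float) * self.stds + self.means


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic expression dataset.

    ``effect_size`` is the distance between adjacent class means in units of
    the within-class standard deviation; ``redundancy_noise`` is the std of
    the noise added to each redundant copy of an informative feature.
    """

    n_samples: int = 60
    n_informative: int = 10
    n_redundant: int = 10
    n_irrelevant: int = 480
    n_classes: int = 2
    effect_size: float = 2.0
    redundancy_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_informative", "n_redundant", "n_irrelevant"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_informative < 1:
            raise ValueError("need at least 1 informative feature")
        if self.redundancy_noise < 0:
            raise ValueError("redundancy_noise must be >= 0")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("need at least 2 samples per class")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_irrelevant


def _parse_numeric_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    """Convert a feature frame to float, reporting the first bad cell."""
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row_label = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ValueError(
                f"{path}: non-numeric or missing value at row {row_label!r}, "
                f"column {col!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return values


def read_matrix(
    path: str | Path,
    label_column: str = "class",
    orientation: str = "samples-in-rows",
) -> ExpressionDataset:
    """Read a delimited (CSV/TSV, sniffed) labeled expression matrix.

    The first column holds sample identifiers (feature identifiers for
    ``features-in-rows`` input, which is transposed so that samples end up
    in rows).  The label column/row is named by ``label_column``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    if orientation not in ("samples-in-rows", "features-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, dtype=str)
    if orientation == "features-in-rows":
        df = df.T
    if label_column not in df.columns:
        raise ValueError(
            f"{path}: label column {label_column!r} not found "
            f"(columns: {list(df.columns)[:8]}...)"
        )
    labels = df[label_column].astype(str).to_numpy()
    if pd.isna(df[label_column]).any():
        raise ValueError(f"{path}: missing values in label column {label_column!r}")
    features = df.drop(columns=[label_column])
    matrix = _parse_numeric_frame(features, str(path))
    return ExpressionDataset(
        matrix,
        labels,
        [str(c) for c in features.columns],
        [str(i) for i in df.index],
    )


def write_matrix(data: ExpressionDataset, path: str | Path, label_column: str = "class") -> None:
    """Write a dataset as CSV (samples in rows, label as the last column)."""
    df = pd.DataFrame(data.matrix, index=data.sample_ids, columns=data.feature_names)
    df[label_column] = data.labels
    df.index.name = "id"
    df.to_csv(path)


def standardize(
    data: ExpressionDataset,
) -> tuple[ExpressionDataset, StandardizationParams]:
    """Per-feature z-scoring with the n-1 (sample) std denominator.

    Constant features map to all-zeros with std recorded as 1, keeping the
    transform total for the flat probes common in expression matrices.
    """
    means = data.matrix.mean(axis=0)
    stds = data.matrix.std(axis=0, ddof=1)
    stds = np.where(stds <= 1e-12, 1.0, stds)
    params = StandardizationParams(means, stds)
    out = ExpressionDataset(
        params.transform(data.matrix),
        data.labels.copy(),
        list(data.feature_names),
        list(data.sample_ids),
    )
    return out, params


def stratified_folds(
    labels: np.ndarray | list, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split as (train_indices, test_indices) pairs.

    If a class has fewer than k samples, k is clamped to the smallest class
    size (with a warning) rather than failing: tiny classes are routine in
    outcome-prediction cohorts.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    k_eff = int(min(k, counts.min()))
    if k_eff < k:
        warnings.warn(
            f"k={k} exceeds the smallest class size {counts.min()}; using k={k_eff}",
            stacklevel=2,
        )
        logger.warning("clamped k from %d to %d", k, k_eff)
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed % (2**32))
    return [(train, test) for train, test in skf.split(np.zeros(labels.size), labels)]


def generate_synthetic(spec: SyntheticSpec) -> ExpressionDataset:
    """Draw a synthetic labeled expression matrix per the spec's recipe.

    Class sizes are as balanced as n_samples allows.  Informative feature
    values for class c are N(mu_c, 1) with adjacent class means separated by
    ``effect_size``; redundant feature j copies informative feature
    (j mod n_informative) plus N(0, redundancy_noise) noise; irrelevant
    features are standard normal, independent of the labels.  Columns are
    randomly permuted; provenance survives in the feature names
    ("inf_*", "red_*", "irr_*").
    """
    rng = np.random.default_rng(spec.seed)
    base, extra = divmod(spec.n_samples, spec.n_classes)
    class_sizes = [base + (1 if c < extra else 0) for c in range(spec.n_classes)]
    labels = np.concatenate(
        [np.full(size, f"class{c}") for c, size in enumerate(class_sizes)]
    )
    class_index = np.concatenate(
        [np.full(size, c) for c, size in enumerate(class_sizes)]
    )

    offsets = (class_index - (spec.n_classes - 1) / 2.0) * spec.effect_size
    informative = (
        rng.standard_normal((spec.n_samples, spec.n_informative)) + offsets[:, None]
    )
    redundant = np.empty((spec.n_samples, spec.n_redundant))
    for j in range(spec.n_redundant):
        src = j % spec.n_informative
        noise = (
            rng.standard_normal(spec.n_samples) * spec.redundancy_noise
            if spec.redundancy_noise > 0
            else 0.0
        )
        redundant[:, j] = informative[:, src] + noise
    irrelevant = rng.standard_normal((spec.n_samples, spec.n_irrelevant))

    matrix = np.hstack([informative, redundant, irrelevant])
    names = (
        [f"inf_{j}" for j in range(spec.n_informative)]
        + [f"red_{j}" for j in range(spec.n_redundant)]
        + [f"irr_{j}" for j in range(spec.n_irrelevant)]
    )
    perm = rng.permutation(spec.n_features)
    matrix = matrix[:, perm]
    names = [names[j] for j in perm]
    sample_ids = [f"s{i}" for i in range(spec.n_samples)]
    return ExpressionDataset(matrix, labels, names, sample_ids)
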