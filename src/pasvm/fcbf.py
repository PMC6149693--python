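"""Fast Correlation-Based Filter (FCBF) feature selection.

FCBF scores every feature against the class by symmetrical uncertainty
(SU, a normalized mutual information in [0, 1]) and then removes features
"predominated" by a stronger correlated feature: feature i predominates j
when SU(i, j) >= SU(j, class).  Continuous features are discretized first —
by default with recursive entropy-minimizing binary splitting under the
Fayyad–Irani MDL stopping criterion, the conventional companion to
SU-based selectors; equal-frequency binning is available as an alternative.

All entropies use base-2 logarithms and empirical (maximum-likelihood)
probabilities, so SU values are comparable to published FCBF numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datasets import ExpressionDataset

__all__ = [
    "DiscretizedFeature",
    "FCBFResult",
    "discretize_mdl",
    "discretize_equal_frequency",
    "symmetrical_uncertainty",
    "fcbf_select",
]


@dataclass
class DiscretizedFeature:
    """Integer bin codes for one feature; n_bins == 1 means the MDL
    criterion judged the feature uninformative (or it is constant)."""

    codes: np.ndarray
    n_bins: int
    cut_points: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        self.cut_points = np.asarray(self.cut_points, dtype=float)
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.cut_points.size != self.n_bins - 1:
            raise ValueError("need exactly n_bins - 1 cut points")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() >= self.n_bins):
            raise ValueError("codes out of range [0, n_bins)")


@dataclass
class FCBFResult:
    selected_indices: list[int]
    su_with_class: np.ndarray
    removed_as_irrelevant: set[int]
    removed_as_redundant: dict[int, int]  # removed index -> predominating index

    @property
    def n_selected(self) -> int:
        return len(self.selected_indices)


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _label_entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    return _entropy_from_counts(counts)


def _best_split(values: np.ndarray, y: np.ndarray, n_classes: int):
    """Cheapest binary split of the (sorted) block: returns
    (cut_index, weighted_child_entropy) or None when no split exists.

    cut_index t splits into [0, t) and [t, n); only boundaries between
    distinct values are candidates.
    """
    n = values.size
    # cumulative class counts along the sorted order
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]

    candidates = np.flatnonzero(values[1:] > values[:-1]) + 1
    if candidates.size == 0:
        return None
    left = cum[candidates - 1]
    right = total - left
    nl = candidates.astype(float)
    nr = n - nl

    def ent(counts, sizes):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = counts / sizes[:, None]
            logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return -(p * logp).sum(axis=1)

    weighted = (nl / n) * ent(left, nl) + (nr / n) * ent(right, nr)
    best = int(np.argmin(weighted))
    return int(candidates[best]), float(weighted[best])


def _mdl_accepts(y: np.ndarray, t: int, n_classes_present: int) -> bool:
    """Fayyad–Irani MDL test for the split of y (sorted block) at index t."""
    n = y.size
    h_s = _label_entropy(y)
    left, right = y[:t], y[t:]
    h1, h2 = _label_entropy(left), _label_entropy(right)
    gain = h_s - (left.size / n) * h1 - (right.size / n) * h2
    k = n_classes_present
    k1 = np.unique(left).size
    k2 = np.unique(right).size
    delta = math.log2(3**k - 2) - (k * h_s - k1 * h1 - k2 * h2)
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def discretize_mdl(values, labels) -> DiscretizedFeature:
    """Entropy-based discretization with the Fayyad–Irani MDL stop rule.

    Recursively bisects the value range at the entropy-minimizing boundary,
    accepting a split only when its information gain exceeds the MDL coding
    cost.  A feature with no acceptable split collapses to a single bin
    (n_bins = 1), which FCBF then treats as carrying zero information.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape or values.ndim != 1:
        raise ValueError("values and labels must be 1-D of equal length")
    if values.size < 2:
        raise ValueError("need at least 2 samples")
    _, y_all = np.unique(labels, return_inverse=True)
    n_classes = int(y_all.max()) + 1

    order = np.argsort(values, kind="stable")
    sv, sy = values[order], y_all[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        block_v, block_y = sv[lo:hi], sy[lo:hi]
        if hi - lo < 2 or np.unique(block_y).size < 2:
            return
        found = _best_split(block_v, block_y, n_classes)
        if found is None:
            return
        t, _ = found
        if not _mdl_accepts(block_y, t, np.unique(block_y).size):
            return
        cuts.append((block_v[t - 1] + block_v[t]) / 2.0)
        recurse(lo, lo + t)
        recurse(lo + t, hi)

    recurse(0, values.size)
    cut_points = np.sort(np.asarray(cuts, dtype=float))
    codes = np.searchsorted(cut_points, values, side="left")
    return DiscretizedFeature(codes, cut_points.size + 1, cut_points)


def discretize_equal_frequency(values, n_bins: int = 10) -> DiscretizedFeature:
    """Quantile (equal-frequency) binning; duplicate quantiles collapse."""
    values = np.asarray(values, dtype=float)
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    cut_points = np.unique(qs)
    # drop cuts outside the open value range (all-equal features -> no cuts)
    cut_points = cut_points[(cut_points > values.min()) & (cut_points < values.max())]
    codes = np.searchsorted(cut_points, values, side="right")
    return DiscretizedFeature(codes, cut_points.size + 1, cut_points)


def symmetrical_uncertainty(x, y) -> float:
    """SU(X, Y) = 2 * IG(X | Y) / (H(X) + H(Y)), in [0, 1].

    Symmetric; 1 for bijectively related non-constant variables; defined as
    0 when both variables are constant (H(X) + H(Y) = 0) so selection stays
    total on degenerate features.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = int(xi.max()) + 1, int(yi.max()) + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xi, yi), 1.0)
    h_x = _entropy_from_counts(joint.sum(axis=1))
    h_y = _entropy_from_counts(joint.sum(axis=0))
    h_xy = _entropy_from_counts(joint.ravel())
    denom = h_x + h_y
    if denom == 0.0:
        return 0.0
    ig = h_x + h_y - h_xy  # mutual information
    return float(min(1.0, max(0.0, 2.0 * ig / denom)))


def fcbf_select(
    data: ExpressionDataset,
    delta: float = 0.0,
    discretizer: str = "mdl",
) -> FCBFResult:
    """Two-stage FCBF selection.

    Stage 1 keeps features with SU(feature, class) > delta, ordered by
    decreasing SU (ties broken by ascending feature index).  Stage 2 walks
    that list and removes every later feature j for which a surviving
    earlier feature i satisfies SU(i, j) >= SU(j, class), recording the
    predominating feature.  delta defaults to 0, i.e. any strictly positive
    class correlation survives stage 1.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if discretizer not in ("mdl", "equal-frequency"):
        raise ValueError(f"unknown discretizer {discretizer!r}")

    _, class_codes = np.unique(data.labels, return_inverse=True)
    p = data.n_features
    codes: list[np.ndarray] = []
    su_class = np.zeros(p)
    for j in range(p):
        col = data.matrix[:, j]
        if discretizer == "mdl":
            disc = discretize_mdl(col, data.labels)
        else:
            disc = discretize_equal_frequency(col)
        codes.append(disc.codes)
        su_class[j] = symmetrical_uncertainty(disc.codes, class_codes)

    relevant = [j for j in range(p) if su_class[j] > delta]
    relevant.sort(key=lambda j: (-su_class[j], j))
    removed_irrelevant = {j for j in range(p) if su_class[j] <= delta}

    selected: list[int] = []
    removed_redundant: dict[int, int] = {}
    remaining = list(relevant)
    while remaining:
        i = remaining.pop(0)
        selected.append(i)
        survivors = []
        for j in remaining:
            if symmetrical_uncertainty(codes[i], codes[j]) >= su_class[j]:
                removed_redundant[j] = i
            else:
                survivors.append(j)
        remaining = survivors

    return FCBFResult(selected, su_class, removed_irrelevant, removed_redundant)
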