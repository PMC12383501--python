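"""Community-composition workflow: Hellinger transform, dissimilarity
matrices, chronological multivariate regression tree, and principal
coordinates ordination.

The regression tree partitions years (its sole explanatory variable is
calendar year, so groups are contiguous blocks); tree size is selected
by V-fold cross-validation with either the minimum-error or the
one-standard-error rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

METRIC_HELLINGER = "hellinger"
METRIC_PERCENT_DIFF = "percentage-difference"


def hellinger_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Square root of within-year relative abundance.

    Each nonzero row of the result has unit sum of squares, making
    Euclidean distances between rows ecologically meaningful.  Zero
    rows stay zero (with a warning).
    """
    values = matrix.to_numpy(float)
    if (values < 0).any():
        raise ValueError("negative values cannot be Hellinger-transformed")
    totals = values.sum(axis=1)
    if (totals == 0).any():
        warnings.warn(
            f"{int((totals == 0).sum())} all-zero row(s) left as zeros",
            stacklevel=2,
        )
    safe = np.where(totals > 0, totals, 1.0)
    out = np.sqrt(values / safe[:, None])
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def _is_hellinger(values: np.ndarray, tol: float = 1e-8) -> bool:
    row_ss = (values**2).sum(axis=1)
    return bool(np.all((np.abs(row_ss - 1.0) < tol) | (row_ss < tol)))


def percentage_difference(u: np.ndarray, v: np.ndarray) -> float:
    """Abundance-based Bray-Curtis-type dissimilarity (B+C)/(2A+B+C)."""
    common = np.minimum(u, v).sum()
    losses = np.clip(u - v, 0, None).sum()
    gains = np.clip(v - u, 0, None).sum()
    denom = 2 * common + losses + gains
    if denom == 0:
        return 0.0
    return float((losses + gains) / denom)


def distance_matrix(matrix: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Pairwise year-to-year dissimilarities.

    ``hellinger`` expects the transformed matrix (Euclidean distance
    between its rows); ``percentage-difference`` expects raw biomass.
    """
    values = matrix.to_numpy(float)
    if metric == METRIC_HELLINGER:
        if not _is_hellinger(values):
            raise ValueError(
                "hellinger metric expects a Hellinger-transformed matrix "
                "(unit row sums of squares)"
            )
        dist = squareform(pdist(values, metric="euclidean"))
    elif metric == METRIC_PERCENT_DIFF:
        if (values < 0).any():
            raise ValueError("percentage difference requires non-negative biomass")
        n = len(values)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dist[i, j] = dist[j, i] = percentage_difference(values[i], values[j])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    out = pd.DataFrame(dist, index=matrix.index, columns=matrix.index)
    out.attrs["metric"] = metric
    return out


# ---------------------------------------------------------------------------
# multivariate regression tree over time


@dataclass(frozen=True)
class MRTResult:
    """Chronological partition of years minimizing within-group variance."""

    splits: tuple[float, ...]  # year thresholds (midpoints), ascending
    groups: pd.Series  # year -> group id (1-based, chronological)
    cv_table: pd.DataFrame  # size, train_rel_error, cv_rel_error, cv_se
    selected_size: int
    rule: str
    seed: int


def _block_ss(prefix: np.ndarray, prefix_sq: np.ndarray, a: int, b: int) -> float:
    """Within-block sum of squared deviations for rows [a, b)."""
    n = b - a
    if n <= 1:
        return 0.0
    total = prefix[b] - prefix[a]
    total_sq = prefix_sq[b] - prefix_sq[a]
    return float(total_sq - (total**2).sum() / n)


def _grow_partitions(Y: np.ndarray, max_leaves: int) -> list[list[int]]:
    """Greedy best-first chronological splitting.

    Returns cut-position lists for sizes 1..m (m <= max_leaves; growth
    stops when no split reduces the objective).  A cut at position c
    separates rows [.., c) from [c, ..).  Ties go to the earliest cut.
    """
    n = len(Y)
    prefix = np.vstack([np.zeros(Y.shape[1]), np.cumsum(Y, axis=0)])
    prefix_sq = np.concatenate([[0.0], np.cumsum((Y**2).sum(axis=1))])

    def ss(a: int, b: int) -> float:
        return _block_ss(prefix, prefix_sq, a, b)

    cuts: list[int] = []
    partitions = [[]]
    tol = 1e-12 * max(ss(0, n), 1.0)
    for _ in range(min(max_leaves, n) - 1):
        bounds = [0] + sorted(cuts) + [n]
        best_gain, best_cut = tol, None
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < 2:
                continue
            parent = ss(a, b)
            for c in range(a + 1, b):
                gain = parent - ss(a, c) - ss(c, b)
                if gain > best_gain + tol:
                    best_gain, best_cut = gain, c
        if best_cut is None:
            break
        cuts.append(best_cut)
        partitions.append(sorted(cuts))
    return partitions


def _partition_error(
    Y_train: np.ndarray,
    years_train: np.ndarray,
    Y_test: np.ndarray,
    years_test: np.ndarray,
    cuts: list[int],
) -> float:
    """Squared prediction error of a fitted partition on held-out years."""
    thresholds = [
        (years_train[c - 1] + years_train[c]) / 2.0 for c in cuts
    ]
    bounds = [0] + list(cuts) + [len(Y_train)]
    means = [
        Y_train[a:b].mean(axis=0) for a, b in zip(bounds[:-1], bounds[1:])
    ]
    leaf = np.searchsorted(thresholds, years_test)
    pred = np.vstack([means[g] for g in leaf])
    return float(((Y_test - pred) ** 2).sum())


def fit_mrt(
    transformed: pd.DataFrame,
    max_leaves: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
    rule: str = "min",
    fold_type: str = "blocks",
) -> MRTResult:
    """Multivariate regression tree of the community on calendar year.

    Split criterion: maximal reduction of the total within-group sum of
    squared deviations of the multivariate response; candidate splits
    are midpoints between consecutive years.  Size is selected by
    V-fold cross-validation (contiguous block folds by default, random
    folds optional) under the minimum-CV-error rule (``rule="min"``) or
    the one-standard-error rule (``rule="1se"``).
    """
    if rule not in ("min", "1se"):
        raise ValueError(f"unknown size-selection rule {rule!r}")
    if fold_type not in ("blocks", "random"):
        raise ValueError(f"unknown fold type {fold_type!r}")
    Y = transformed.to_numpy(float)
    years = transformed.index.to_numpy(float)
    n = len(Y)
    if n < 4:
        raise ValueError("need at least 4 years for a regression tree")
    max_leaves = min(max_leaves, n)
    partitions = _grow_partitions(Y, max_leaves)
    ss_total = float(((Y - Y.mean(axis=0)) ** 2).sum())

    prefix = np.vstack([np.zeros(Y.shape[1]), np.cumsum(Y, axis=0)])
    prefix_sq = np.concatenate([[0.0], np.cumsum((Y**2).sum(axis=1))])

    def within(cuts: list[int]) -> float:
        bounds = [0] + list(cuts) + [n]
        return sum(
            _block_ss(prefix, prefix_sq, a, b)
            for a, b in zip(bounds[:-1], bounds[1:])
        )

    folds = np.array_split(np.arange(n), min(cv_folds, n))
    if fold_type == "random":
        order = np.random.default_rng(seed).permutation(n)
        folds = np.array_split(order, min(cv_folds, n))

    rows = []
    degenerate = ss_total == 0
    for size_idx, cuts in enumerate(partitions):
        size = size_idx + 1
        train_err = within(cuts) / ss_total if not degenerate else 0.0
        fold_errs = []
        for fold in folds:
            mask = np.ones(n, bool)
            mask[fold] = False
            if mask.sum() < 2:
                continue
            sub_parts = _grow_partitions(Y[mask], size)
            sub_cuts = sub_parts[min(size, len(sub_parts)) - 1]
            fold_errs.append(
                _partition_error(Y[mask], years[mask], Y[~mask], years[~mask], sub_cuts)
            )
        cv_err = sum(fold_errs) / ss_total if not degenerate else 0.0
        rel = (
            np.array(fold_errs) * len(fold_errs) / ss_total
            if not degenerate
            else np.zeros(len(fold_errs))
        )
        cv_se = float(rel.std(ddof=1) / np.sqrt(len(rel))) if len(rel) > 1 else 0.0
        rows.append(
            {
                "size": size,
                "train_rel_error": train_err,
                "cv_rel_error": cv_err,
                "cv_se": cv_se,
            }
        )
    cv_table = pd.DataFrame(rows)

    errors = cv_table["cv_rel_error"].to_numpy()
    best = int(np.argmin(errors))
    if rule == "1se":
        limit = errors[best] + cv_table["cv_se"].iloc[best]
        best = int(np.argmax(errors <= limit))  # smallest qualifying size
    selected_size = int(cv_table["size"].iloc[best])

    cuts = partitions[selected_size - 1]
    thresholds = tuple((years[c - 1] + years[c]) / 2.0 for c in cuts)
    labels = np.searchsorted(thresholds, years) + 1
    groups = pd.Series(labels, index=transformed.index, name="group")
    return MRTResult(
        splits=thresholds,
        groups=groups,
        cv_table=cv_table,
        selected_size=selected_size,
        rule=rule,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# principal coordinates analysis


@dataclass(frozen=True)
class PCoAResult:
    """Metric ordination of a distance matrix.

    ``coordinates`` holds axes for positive eigenvalues only; negative
    eigenvalues (possible for non-Euclidean dissimilarities) are
    reported in ``eigenvalues`` but not corrected.
    """

    eigenvalues: np.ndarray  # all eigenvalues, descending
    coordinates: pd.DataFrame  # years x positive axes
    proportions: np.ndarray  # eigenvalue / sum of positive eigenvalues

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def pcoa(dist: pd.DataFrame) -> PCoAResult:
    """Gower double-centering followed by eigen-decomposition.

    Coordinates are eigenvectors scaled by the square roots of their
    (positive) eigenvalues, so inter-point Euclidean distances in the
    full space reproduce the input distances when the input is
    Euclidean-embeddable.
    """
    D = dist.to_numpy(float)
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * centering @ (D**2) @ centering
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = np.abs(eigval).max() * 1e-10 if np.abs(eigval).max() > 0 else 0.0
    positive = eigval > tol
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    # deterministic axis orientation: largest-magnitude loading positive
    for j in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, j]))
        if coords[pivot, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigval[positive].sum()
    proportions = (
        eigval[positive] / pos_sum if pos_sum > 0 else np.zeros(positive.sum())
    )
    frame = pd.DataFrame(
        coords,
        index=dist.index,
        columns=[f"axis{j + 1}" for j in range(coords.shape[1])],
    )
    return PCoAResult(eigenvalues=eigval, coordinates=frame, proportions=proportions)
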