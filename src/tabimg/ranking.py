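"""Pairwise-distance rank matrices for features and pixels.

The layout optimizer works entirely on two N-by-N rank matrices:

* ``R`` — ranks of the N(N-1)/2 pairwise distances between feature columns;
* ``Q`` — ranks of the pairwise distances between pixel positions of an
  Nr-by-Nc grid, pixels linearized row by row.

Both matrices are symmetric with a zero diagonal, and small distances get
small ranks (ascending ranking).  Tied distances — ubiquitous on pixel
grids, where many pairs share the same geometric distance — receive their
average rank by default, which keeps the lower-triangle rank sum equal to
K(K+1)/2 for K = N(N-1)/2 pairs regardless of ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .dataset import TabularDataset

__all__ = [
    "ImageGrid",
    "DistanceSpec",
    "RankMatrix",
    "select_top_variance_features",
    "pad_or_trim_to_grid",
    "feature_distance_rank_matrix",
    "pixel_distance_rank_matrix",
    "pixel_coordinates",
]

FEATURE_METRICS = ("euclidean", "one_minus_correlation", "one_minus_jaccard")
PIXEL_METRICS = ("euclidean", "manhattan")
TIE_METHODS = ("average", "ordinal")


@dataclass(frozen=True)
class ImageGrid:
    """Target image geometry: ``n_rows`` x ``n_cols`` pixels, one feature per pixel."""

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def size(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class DistanceSpec:
    """Distance measures used to build the rank matrices.

    ``one_minus_correlation`` is 1 - Pearson rho, suited to continuous
    profiles; ``one_minus_jaccard`` is only valid for binary tables.  For
    pixels, Manhattan distance is an alternative to Euclidean.  ``ties``
    selects the ranking rule for equal distances: ``"average"`` (default)
    or ``"ordinal"`` (first-come-first-ranked by pair index).
    """

    feature_metric: str = "euclidean"
    pixel_metric: str = "euclidean"
    ties: str = "average"

    def __post_init__(self) -> None:
        if self.feature_metric not in FEATURE_METRICS:
            raise ValueError(f"feature_metric must be one of {FEATURE_METRICS}")
        if self.pixel_metric not in PIXEL_METRICS:
            raise ValueError(f"pixel_metric must be one of {PIXEL_METRICS}")
        if self.ties not in TIE_METHODS:
            raise ValueError(f"ties must be one of {TIE_METHODS}")


@dataclass
class RankMatrix:
    """Symmetric N-by-N matrix of ascending distance ranks with zero diagonal."""

    ranks: np.ndarray

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=float)
        if self.ranks.ndim != 2 or self.ranks.shape[0] != self.ranks.shape[1]:
            raise ValueError("rank matrix must be square")
        if not np.allclose(self.ranks, self.ranks.T):
            raise ValueError("rank matrix must be symmetric")
        if np.any(np.diag(self.ranks) != 0):
            raise ValueError("rank matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.ranks.shape[0]

    @classmethod
    def from_condensed(cls, condensed_ranks: np.ndarray) -> "RankMatrix":
        full = squareform(np.asarray(condensed_ranks, dtype=float))
        np.fill_diagonal(full, 0.0)
        return cls(full)


def as_rank_array(matrix) -> np.ndarray:
    """Accept a RankMatrix or a bare square array; return the ndarray view."""
    arr = matrix.ranks if isinstance(matrix, RankMatrix) else np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("expected a square rank matrix")
    return arr


# ----------------------------------------------------------------------
# Feature selection and grid matching
# ----------------------------------------------------------------------

def select_top_variance_features(data: TabularDataset, k: int) -> TabularDataset:
    """Keep the ``k`` features with the largest variance across samples.

    Column order among the kept features is preserved.  Ties at the cutoff
    are resolved by first occurrence in the table.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if k > data.n_features:
        raise ValueError(f"k={k} exceeds the number of features ({data.n_features})")
    variances = np.var(data.values, axis=0)
    # stable sort on descending variance keeps first-occurrence order for ties
    order = np.argsort(-variances, kind="stable")[:k]
    return data.select_features(np.sort(order))


def pad_or_trim_to_grid(data: TabularDataset, grid: ImageGrid,
                        allow_trim: bool = False) -> TabularDataset:
    """Match the feature count to the grid size.

    Fewer features than pixels: append all-zero pseudo-features.  More
    features than pixels: keep the top-variance subset, but only when the
    caller opts in with ``allow_trim`` — silently discarding columns would
    be surprising.
    """
    n, target = data.n_features, grid.size
    if n == target:
        return data
    if n > target:
        if not allow_trim:
            raise ValueError(
                f"{n} features do not fit a {grid.n_rows}x{grid.n_cols} grid "
                f"({target} pixels); pass allow_trim=True to keep the "
                f"{target} highest-variance features"
            )
        return select_top_variance_features(data, target)
    pad = target - n
    existing = set(data.feature_names)
    pad_names = []
    i = 0
    while len(pad_names) < pad:
        name = f"_pad{i}"
        if name not in existing:
            pad_names.append(name)
        i += 1
    values = np.hstack([data.values, np.zeros((data.n_samples, pad))])
    return TabularDataset(values, sample_ids=list(data.sample_ids),
                          feature_names=list(data.feature_names) + pad_names)


# ----------------------------------------------------------------------
# Rank-matrix construction
# ----------------------------------------------------------------------

def _rank_condensed(distances: np.ndarray, ties: str) -> np.ndarray:
    method = {"average": "average", "ordinal": "ordinal"}[ties]
    return rankdata(distances, method=method)


def feature_distance_rank_matrix(data: TabularDataset,
                                 spec: DistanceSpec | None = None) -> RankMatrix:
    """Rank matrix ``R`` of pairwise distances between feature columns."""
    spec = spec or DistanceSpec()
    columns = data.values.T  # features as vectors over samples
    if spec.feature_metric == "euclidean":
        d = pdist(columns, metric="euclidean")
    elif spec.feature_metric == "one_minus_correlation":
        sd = np.std(columns, axis=1)
        if np.any(sd == 0):
            j = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(
                f"feature {data.feature_names[j]!r} is constant; "
                "1 - correlation is undefined for constant features"
            )
        d = pdist(columns, metric="correlation")
    else:  # one_minus_jaccard
        unique = np.unique(data.values)
        if not np.all(np.isin(unique, (0.0, 1.0))):
            raise ValueError("one_minus_jaccard requires a binary (0/1) table")
        d = pdist(columns.astype(bool), metric="jaccard")
    if not np.all(np.isfinite(d)):
        i, j = _offending_pair(d, data.n_features)
        raise ValueError(
            f"non-finite distance between features "
            f"{data.feature_names[i]!r} and {data.feature_names[j]!r}"
        )
    return RankMatrix.from_condensed(_rank_condensed(d, spec.ties))


def _offending_pair(condensed: np.ndarray, n: int) -> tuple[int, int]:
    flat = int(np.flatnonzero(~np.isfinite(condensed))[0])
    # invert the condensed index to (i, j), i < j
    idx = flat
    for i in range(n - 1):
        row_len = n - i - 1
        if idx < row_len:
            return i, i + 1 + idx
        idx -= row_len
    raise AssertionError("condensed index out of range")  # pragma: no cover


def pixel_coordinates(grid: ImageGrid) -> np.ndarray:
    """Integer (row, col) coordinates of the grid pixels in row-major order.

    Pixel ``i`` (0-based) sits at row ``i // n_cols`` and column
    ``i % n_cols``.  Coordinates are unit-spaced; only relative distances
    matter, so the origin is immaterial.
    """
    rows, cols = np.divmod(np.arange(grid.size), grid.n_cols)
    return np.column_stack([rows, cols]).astype(float)


def pixel_distance_rank_matrix(grid: ImageGrid,
                               spec: DistanceSpec | None = None) -> RankMatrix:
    """Rank matrix ``Q`` of pairwise distances between pixel coordinates."""
    spec = spec or DistanceSpec()
    if grid.size < 2:
        raise ValueError("grid must contain at least 2 pixels")
    coords = pixel_coordinates(grid)
    metric = {"euclidean": "euclidean", "manhattan": "cityblock"}[spec.pixel_metric]
    d = pdist(coords, metric=metric)
    return RankMatrix.from_condensed(_rank_condensed(d, spec.ties))
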