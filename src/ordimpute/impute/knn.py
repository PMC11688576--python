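"""K-nearest-neighbor imputation with missing-aware Euclidean distance.

Distances between partially observed rows are computed over the
coordinates observed in both rows and rescaled by sqrt(p / n_shared),
so rows sharing few coordinates are not spuriously close.  Each missing
cell is filled with the uniform mean of its k nearest donor rows (rows
where that column is observed); distance ties break toward the lower row
index, and a cell with no eligible donor falls back to the column mean.

Items all live on one 1..5 scale, so no standardization is applied.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import nan_euclidean_distances

from .base import BaseImputer, check_incomplete_matrix

__all__ = ["KNNImputer", "knn_impute"]


class KNNImputer(BaseImputer):
    """Nearest-neighbor mean imputer (k=3, Euclidean, uniform weights).

    Donor rows come from the matrix passed to ``fit``.
    """

    def __init__(self, n_neighbors: int = 3):
        self.n_neighbors = n_neighbors

    def _fit(self, X: np.ndarray) -> None:
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        self._donors = X
        self._donor_col_means = np.nanmean(X, axis=0)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        donors = self._donors
        same = donors is X or (
            donors.shape == X.shape and np.array_equal(donors, X, equal_nan=True)
        )
        # sqrt(p / n_shared)-scaled Euclidean; +inf when no shared coordinate
        with np.errstate(invalid="ignore"):
            dist = nan_euclidean_distances(X, donors, missing_values=np.nan)
        dist = np.where(np.isnan(dist), np.inf, dist)
        out = X.copy()
        for i, j in zip(*np.nonzero(np.isnan(X))):
            eligible = ~np.isnan(donors[:, j]) & np.isfinite(dist[i])
            if same:
                eligible[i] = False
            idx = np.flatnonzero(eligible)
            if idx.size == 0:
                out[i, j] = self._donor_col_means[j]
                continue
            # stable sort on distance -> ties broken by lower row index
            order = idx[np.argsort(dist[i, idx], kind="stable")]
            chosen = order[: self.n_neighbors]
            out[i, j] = donors[chosen, j].mean()
        return out


def knn_impute(X, k: int = 3) -> np.ndarray:
    """Functional one-shot KNN imputation (donors = X itself)."""
    X = check_incomplete_matrix(X)
    return KNNImputer(n_neighbors=k).fit(X).transform(X)
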