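"""Synthetic Likert-scale data generation and scale CSV input/output.

The generator emulates a short unidimensional stress questionnaire (ten
positively inter-correlated items scored 1..5) with a one-factor
normal-ogive model: each respondent carries a latent trait ``z ~ N(0, 1)``,
each item ``j`` a loading ``lambda_j``; the continuous response

    y_ij = lambda_j * z_i + sqrt(1 - lambda_j**2) * eps_ij,   eps ~ N(0, 1)

is cut at fixed thresholds into ordered categories.  With this
parameterisation ``y_ij`` is standard normal marginally, so thresholds are
interpretable as normal quantiles and the inter-item polychoric correlation
equals ``lambda_j * lambda_k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScaleSpec",
    "generate_scale_data",
    "subsample_rows",
    "read_scale_csv",
    "write_scale_csv",
]


def _default_thresholds(n_categories: int) -> np.ndarray:
    """Normal quantiles of equally spaced cumulative probabilities.

    For 5 categories: Phi^-1 of (0.2, 0.4, 0.6, 0.8), i.e. equal 20%
    marginal mass per category when loadings are irrelevant (marginals of
    y are N(0,1) regardless of the loading).
    """
    probs = np.arange(1, n_categories) / n_categories
    return stats.norm.ppf(probs)


@dataclass
class ScaleSpec:
    """Parameters of the one-factor ordinal generator.

    Parameters
    ----------
    n_items : int
        Number of questionnaire items (columns), default 10.
    n_categories : int
        Number of ordered response categories, default 5 (scores 1..5).
    loadings : array-like of shape (n_items,), optional
        Factor loadings, each in (-1, 1).  Default 0.6 everywhere: items
        are clearly correlated (latent r = 0.36) without being degenerate.
    thresholds : array-like of shape (n_categories - 1,), optional
        Strictly increasing cut points on the latent scale.  Default:
        quantile-symmetric (equal marginal category probabilities).
    reverse_items : frozenset of int
        Indices of reverse-keyed items; their loading sign is flipped.
    """

    n_items: int = 10
    n_categories: int = 5
    loadings: np.ndarray | None = None
    thresholds: np.ndarray | None = None
    reverse_items: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be a positive integer")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        if self.loadings is None:
            self.loadings = np.full(self.n_items, 0.6)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape != (self.n_items,):
            raise ValueError(
                f"loadings must have length n_items={self.n_items}, "
                f"got shape {self.loadings.shape}"
            )
        if np.any(np.abs(self.loadings) >= 1.0):
            raise ValueError("every |loading| must be < 1")
        if self.thresholds is None:
            self.thresholds = _default_thresholds(self.n_categories)
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.shape != (self.n_categories - 1,):
            raise ValueError(
                "thresholds must have length n_categories - 1 = "
                f"{self.n_categories - 1}, got shape {self.thresholds.shape}"
            )
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        self.reverse_items = frozenset(self.reverse_items)
        bad = [i for i in self.reverse_items if not 0 <= i < self.n_items]
        if bad:
            raise ValueError(f"reverse_items indices out of range: {bad}")

    @property
    def signed_loadings(self) -> np.ndarray:
        lam = self.loadings.copy()
        if self.reverse_items:
            idx = sorted(self.reverse_items)
            lam[idx] = -lam[idx]
        return lam

    def item_names(self) -> list[str]:
        return [f"item{j + 1}" for j in range(self.n_items)]


def generate_scale_data(
    spec: ScaleSpec, n: int, seed: int | None = None
) -> np.ndarray:
    """Draw an ``n x n_items`` integer matrix of ordinal scores.

    Returns an int array with entries in ``1..spec.n_categories``.
    Deterministic under ``seed``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    lam = spec.signed_loadings
    z = rng.standard_normal(n)
    eps = rng.standard_normal((n, spec.n_items))
    y = z[:, None] * lam[None, :] + np.sqrt(1.0 - lam**2)[None, :] * eps
    # category = 1 + number of thresholds strictly below y
    cats = 1 + np.searchsorted(spec.thresholds, y).reshape(n, spec.n_items)
    return cats.astype(np.int64)


def subsample_rows(data: np.ndarray, size: int, seed: int | None = None) -> np.ndarray:
    """Sample ``size`` distinct rows uniformly without replacement."""
    data = np.asarray(data)
    if size < 1:
        raise ValueError("size must be positive")
    if size > data.shape[0]:
        raise ValueError(
            f"cannot draw {size} rows without replacement from {data.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(data.shape[0], size=size, replace=False)
    return data[idx].copy()


def write_scale_csv(data: np.ndarray, path, item_names: list[str] | None = None) -> None:
    """Write an ordinal matrix as a header-row CSV of integers."""
    data = np.asarray(data)
    if item_names is None:
        item_names = [f"item{j + 1}" for j in range(data.shape[1])]
    pd.DataFrame(data, columns=item_names).to_csv(path, index=False)


def read_scale_csv(
    path, category_min: int = 1, category_max: int = 5
) -> tuple[np.ndarray, list[str]]:
    """Read a scale CSV, validating integer cells within the category range.

    Returns ``(values, item_names)``.  Raises ``ValueError`` naming the
    offending row/column on a non-integer or out-of-range cell.
    """
    df = pd.read_csv(path, header=0)
    if df.columns.str.match(r"^\d+(\.\d+)?$").all():
        raise ValueError(f"{path}: first row looks numeric; a header row is required")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            i = int(numeric.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric or empty cell at row {i}, column {col!r}"
            )
        as_int = numeric.round().astype(np.int64)
        frac = (numeric - as_int).abs()
        if (frac > 0).any():
            i = int((frac > 0).idxmax())
            raise ValueError(
                f"{path}: non-integer cell {numeric[i]!r} at row {i}, column {col!r}"
            )
        out_of_range = (as_int < category_min) | (as_int > category_max)
        if out_of_range.any():
            i = int(out_of_range.idxmax())
            raise ValueError(
                f"{path}: value {int(as_int[i])} at row {i}, column {col!r} "
                f"outside [{category_min}, {category_max}]"
            )
        values[:, j] = as_int.to_numpy()
    return values, list(df.columns)
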