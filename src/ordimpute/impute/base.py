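"""Shared imputer interface.

Every imputer is an sklearn-style transformer: ``fit(X)`` learns whatever
the method needs from an incomplete matrix (NaN = missing), ``transform(X)``
returns a complete copy.  Two contracts hold for all of them:

* pass-through: observed cells are returned bit-identical;
* completeness: the output contains no NaN.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["BaseImputer", "check_incomplete_matrix"]


def check_incomplete_matrix(
    X, require_observed_columns: bool = True
) -> np.ndarray:
    """Validate and return a float copy of an incomplete matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-d matrix, got ndim={X.ndim}")
    if np.isinf(X).any():
        raise ValueError("matrix contains infinite values")
    if require_observed_columns:
        fully_missing = np.flatnonzero(np.isnan(X).all(axis=0))
        if fully_missing.size:
            raise ValueError(
                f"column(s) {fully_missing.tolist()} have no observed values"
            )
    return X.copy()


class BaseImputer(TransformerMixin, BaseEstimator):
    """Base class enforcing the pass-through and completeness contracts."""

    def fit(self, X, y=None):
        X = check_incomplete_matrix(X)
        self.n_features_in_ = X.shape[1]
        self._fit(X)
        return self

    def transform(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self)
        X = check_incomplete_matrix(X, require_observed_columns=False)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, imputer was fitted with "
                f"{self.n_features_in_}"
            )
        observed = ~np.isnan(X)
        out = self._transform(X)
        # pass-through contract, enforced regardless of the method
        out[observed] = X[observed]
        if np.isnan(out).any():
            raise RuntimeError(
                f"{type(self).__name__} left NaN cells in its output"
            )
        return out

    # subclasses implement these two
    def _fit(self, X: np.ndarray) -> None:  # pragma: no cover - abstract
        raise NotImplementedError

    def _transform(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError
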