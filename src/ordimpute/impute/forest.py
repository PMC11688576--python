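"""Iterative random-forest imputation (the missForest algorithm).

Missing cells are initialized with column means; columns are then visited
in ascending order of missing count, each imputed by a regression random
forest trained on the rows where that column is observed, with all other
columns (at their current imputed values) as predictors.  Sweeps repeat
until the relative sum of squared differences between consecutive
imputations,

    delta = sum((X_new - X_old)^2) / sum(X_new^2)   over originally
                                                    missing cells,

increases, at which point the imputation from before the increase is
returned; a sweep cap (default 10) bounds the loop.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .base import BaseImputer, check_incomplete_matrix

__all__ = ["MissForestImputer", "forest_impute"]


class MissForestImputer(BaseImputer):
    """missForest-style iterative random-forest imputer.

    Parameters
    ----------
    n_trees : int
        Trees per forest, default 100.
    max_iter : int
        Sweep cap, default 10.
    random_state : int or None
        Seeds the forests (one derived seed per column fit).
    mtry : int or None
        Predictors tried per split; None uses the regression default
        max(1, floor(p_predictors / 3)).

    Attributes
    ----------
    n_iter_ : sweeps actually used for the returned imputation.
    deltas_ : the relative-difference sequence, one entry per sweep.
    oob_scores_ : per-sweep mean out-of-bag R^2 across column forests
        (diagnostic only; not used for stopping).
    """

    def __init__(
        self,
        n_trees: int = 100,
        max_iter: int = 10,
        random_state: int | None = None,
        mtry: int | None = None,
    ):
        self.n_trees = n_trees
        self.max_iter = max_iter
        self.random_state = random_state
        self.mtry = mtry

    def _fit(self, X: np.ndarray) -> None:
        if self.n_trees < 1 or self.max_iter < 1:
            raise ValueError("n_trees and max_iter must be >= 1")
        self._fit_X = X

    def _transform(self, X: np.ndarray) -> np.ndarray:
        missing = np.isnan(X)
        if not missing.any():
            self.n_iter_ = 0
            self.deltas_ = []
            self.oob_scores_ = []
            return X.copy()
        n, p = X.shape
        rng = np.random.default_rng(self.random_state)
        col_means = np.nanmean(X, axis=0)
        current = np.where(missing, col_means, X)
        # ascending missing count, ties by column index (argsort is stable)
        order = np.argsort(missing.sum(axis=0), kind="stable")
        order = [int(j) for j in order if missing[:, j].any()]
        mtry = self.mtry
        if mtry is None:
            mtry = max(1, (p - 1) // 3)

        deltas: list[float] = []
        oob: list[float] = []
        previous = current.copy()
        for sweep in range(1, self.max_iter + 1):
            sweep_oob = []
            for j in order:
                obs = ~missing[:, j]
                predictors = np.delete(current, j, axis=1)
                forest = RandomForestRegressor(
                    n_estimators=self.n_trees,
                    max_features=mtry,
                    bootstrap=True,
                    # OOB R^2 is unreliable with few trees (rows may have
                    # no out-of-bag tree); skip the diagnostic there
                    oob_score=self.n_trees >= 20,
                    random_state=int(rng.integers(2**31 - 1)),
                    n_jobs=1,
                )
                y = current[obs, j]
                if np.ptp(y) == 0.0:
                    # zero-variance response: forest would predict the
                    # constant anyway; short-circuit (oob R^2 undefined)
                    current[missing[:, j], j] = y[0]
                    continue
                forest.fit(predictors[obs], y)
                current[missing[:, j], j] = forest.predict(
                    predictors[missing[:, j]]
                )
                if hasattr(forest, "oob_score_"):
                    sweep_oob.append(forest.oob_score_)
            oob.append(float(np.mean(sweep_oob)) if sweep_oob else np.nan)
            num = float(np.sum((current[missing] - previous[missing]) ** 2))
            den = float(np.sum(current[missing] ** 2))
            delta = num / den if den > 0 else 0.0
            deltas.append(delta)
            if sweep > 1 and delta > deltas[-2]:
                # divergence: return the imputation from before the increase
                self.n_iter_ = sweep - 1
                self.deltas_ = deltas
                self.oob_scores_ = oob
                return previous
            previous = current.copy()
        self.n_iter_ = self.max_iter
        self.deltas_ = deltas
        self.oob_scores_ = oob
        return current


def forest_impute(
    X, n_trees: int = 100, max_iter: int = 10, seed: int | None = None
) -> np.ndarray:
    """Functional one-shot missForest imputation."""
    X = check_incomplete_matrix(X)
    imp = MissForestImputer(n_trees=n_trees, max_iter=max_iter, random_state=seed)
    return imp.fit(X).transform(X)
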