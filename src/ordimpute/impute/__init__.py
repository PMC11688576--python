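"""Imputer estimators and the name registry used by the benchmark runner."""

from __future__ import annotations

import numpy as np

from .autoencoder import AutoencoderImputer, autoencoder_impute
from .base import BaseImputer, check_incomplete_matrix
from .em import EMImputer, MvnParams, em_fit, em_impute
from .forest import MissForestImputer, forest_impute
from .knn import KNNImputer, knn_impute
from .remasker import ReMaskerImputer, remask_select, remasker_impute
from .simple import ColumnStatImputer, IdentityImputer, column_stat_impute

__all__ = [
    "BaseImputer",
    "ColumnStatImputer",
    "IdentityImputer",
    "EMImputer",
    "KNNImputer",
    "MissForestImputer",
    "AutoencoderImputer",
    "ReMaskerImputer",
    "MvnParams",
    "column_stat_impute",
    "em_fit",
    "em_impute",
    "knn_impute",
    "forest_impute",
    "autoencoder_impute",
    "remasker_impute",
    "remask_select",
    "check_incomplete_matrix",
    "REGISTRY",
    "make_imputer",
    "impute",
]

# factory(seed, **overrides) -> estimator; seed=None keeps the method
# deterministic where it has no randomness (mean/median/knn)
REGISTRY = {
    "mean": lambda seed=None, **kw: ColumnStatImputer(stat="mean", **kw),
    "median": lambda seed=None, **kw: ColumnStatImputer(stat="median", **kw),
    "em": lambda seed=None, **kw: EMImputer(random_state=seed, **kw),
    "knn": lambda seed=None, **kw: KNNImputer(**kw),
    "missforest": lambda seed=None, **kw: MissForestImputer(random_state=seed, **kw),
    "autoencoder": lambda seed=None, **kw: AutoencoderImputer(random_state=seed, **kw),
    "remasker": lambda seed=None, **kw: ReMaskerImputer(random_state=seed, **kw),
    "identity": lambda seed=None, **kw: IdentityImputer(**kw),
}


def make_imputer(name: str, seed: int | None = None, **overrides) -> BaseImputer:
    """Instantiate a registered imputer by name."""
    try:
        factory = REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown imputer {name!r}; registered: {sorted(REGISTRY)}"
        ) from None
    return factory(seed=seed, **overrides)


def impute(X, method: str, seed: int | None = None, **overrides) -> np.ndarray:
    """One-shot imputation through the shared registry contract."""
    X = check_incomplete_matrix(X)
    est = make_imputer(method, seed=seed, **overrides)
    return est.fit(X).transform(X)
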