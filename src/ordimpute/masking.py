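"""MCAR and MAR missingness mask generation and application.

MCAR: every cell is hidden independently with a fixed Bernoulli rate.

MAR: a random subset of "pillar" columns is kept fully observed; the
remaining cells are hidden with a per-row probability given by a logistic
model on the (standardized) pillar values with random N(0, 1) weights.  The
intercept is calibrated by bisection so that the *overall* expected missing
fraction of the matrix equals the nominal rate, which keeps MCAR and MAR
conditions comparable at equal nominal rates.

Missing marker: IEEE NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MaskResult",
    "mcar_mask",
    "mar_mask",
    "fit_mar_intercept",
    "apply_mask",
]


@dataclass(frozen=True)
class MaskResult:
    """A generated missingness mask plus its provenance.

    ``mask`` is boolean, True = hidden.  ``achieved_rate`` is the realized
    fraction of hidden cells, ``target_rate`` the nominal one.
    """

    mask: np.ndarray
    mechanism: str
    target_rate: float
    seed: int | None
    pillar_columns: tuple[int, ...] = ()

    @property
    def achieved_rate(self) -> float:
        return float(self.mask.mean())


def _check_rate(rate: float) -> None:
    if not 0.0 < rate < 1.0:
        raise ValueError(f"rate must lie in (0, 1), got {rate}")


def mcar_mask(n: int, p: int, rate: float, seed: int | None = None) -> MaskResult:
    """Independent Bernoulli(rate) mask over an n x p grid."""
    _check_rate(rate)
    rng = np.random.default_rng(seed)
    mask = rng.random((n, p)) < rate
    return MaskResult(mask=mask, mechanism="MCAR", target_rate=rate, seed=seed)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable on both tails
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def fit_mar_intercept(
    scores: np.ndarray, target: float, tol: float = 1e-6, max_iter: int = 200
) -> float:
    """Bisection for the intercept b with mean(sigmoid(scores + b)) = target.

    The mean of sigmoids is continuous and strictly increasing in ``b``, so
    bisection over [-50, 50] (where sigmoid saturates to 0/1 at double
    precision) always brackets the root.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must lie in (0, 1), got {target}")
    lo, hi = -50.0, 50.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        attained = float(_sigmoid(scores + mid).mean())
        if abs(attained - target) <= tol:
            return mid
        if attained < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mar_mask(
    data: np.ndarray,
    rate: float,
    observed_fraction: float = 0.3,
    seed: int | None = None,
    weights: np.ndarray | None = None,
) -> MaskResult:
    """Logistic MAR mask driven by fully observed pillar columns.

    Parameters
    ----------
    data : complete (n, p) matrix whose values drive the missingness.
    rate : nominal overall missing fraction of the whole matrix.
    observed_fraction : fraction of columns kept fully observed
        (``ceil(observed_fraction * p)`` pillars), default 0.3.
    weights : optional fixed weight vector over pillar columns (test hook);
        drawn N(0, I) when None.
    """
    data = np.asarray(data, dtype=float)
    _check_rate(rate)
    if not 0.0 < observed_fraction < 1.0:
        raise ValueError("observed_fraction must lie in (0, 1)")
    n, p = data.shape
    if p < 2:
        raise ValueError("MAR masking needs p >= 2 columns")
    rng = np.random.default_rng(seed)
    n_pillars = math.ceil(observed_fraction * p)
    if n_pillars >= p:
        raise ValueError("observed_fraction leaves no column to mask")
    pillars = np.sort(rng.choice(p, size=n_pillars, replace=False))
    # nominal overall rate -> rate on the maskable columns only
    rate_adj = rate * p / (p - n_pillars)
    if rate_adj >= 1.0:
        raise ValueError(
            f"target rate {rate} unattainable: {n_pillars} fully observed "
            f"pillar columns would require per-cell rate {rate_adj:.3f} >= 1"
        )
    x = data[:, pillars]
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    if weights is None:
        weights = rng.standard_normal(n_pillars)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n_pillars,):
            raise ValueError(
                f"weights must have shape ({n_pillars},), got {weights.shape}"
            )
    scores = x @ weights
    b = fit_mar_intercept(scores, rate_adj)
    prob = _sigmoid(scores + b)
    mask = rng.random((n, p)) < prob[:, None]
    mask[:, pillars] = False
    return MaskResult(
        mask=mask,
        mechanism="MAR",
        target_rate=rate,
        seed=seed,
        pillar_columns=tuple(int(c) for c in pillars),
    )


def apply_mask(data: np.ndarray, mask: MaskResult | np.ndarray) -> np.ndarray:
    """Return a float copy of ``data`` with NaN at masked cells."""
    boolmask = mask.mask if isinstance(mask, MaskResult) else np.asarray(mask, bool)
    data = np.asarray(data)
    if boolmask.shape != data.shape:
        raise ValueError(
            f"mask shape {boolmask.shape} does not match data shape {data.shape}"
        )
    out = data.astype(float, copy=True)
    out[boolmask] = np.nan
    return out
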