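"""Rounding to the ordinal scale and RMSE scoring of imputations.

The benchmark metric is the root mean squared error between the complete
ground-truth matrix X and the imputed matrix X-hat,

    RMSE = sqrt( (1 / (n p)) * sum_ij (x_ij - xhat_ij)^2 ),

computed over all n*p cells after rounding imputed values to the nearest
integer and clipping into the 1..5 scale.  ``rmse_masked`` restricts the
average to the hidden cells; with pass-through imputers the two are linked
by rmse_full = rmse_masked * sqrt(m / (n p)) where m is the hidden count.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ResultRecord",
    "round_clip",
    "rmse_full",
    "rmse_masked",
    "aggregate",
    "records_to_frame",
]


@dataclass(frozen=True)
class ResultRecord:
    """One (method, mechanism, rate, n, replicate) -> RMSE observation."""

    method: str
    mechanism: str
    rate: float
    n: int
    replicate: int
    seed: int
    rmse_full: float
    rmse_masked: float
    achieved_rate: float


def round_clip(xhat: np.ndarray, lo: int = 1, hi: int = 5) -> np.ndarray:
    """Round half-away-from-zero to integers, then clip into [lo, hi].

    Half-away-from-zero (2.5 -> 3) rather than banker's rounding, which
    would bias imputations toward even categories.  Idempotent.
    """
    if lo > hi:
        raise ValueError(f"lo={lo} > hi={hi}")
    xhat = np.asarray(xhat, dtype=float)
    if np.isnan(xhat).any():
        raise ValueError("round_clip requires a complete matrix (no NaN)")
    rounded = np.sign(xhat) * np.floor(np.abs(xhat) + 0.5)
    return np.clip(rounded, lo, hi)


def rmse_full(x: np.ndarray, xhat: np.ndarray) -> float:
    """RMSE over all n*p cells of the matrix."""
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    return float(np.sqrt(np.mean((x - xhat) ** 2)))


def rmse_masked(x: np.ndarray, xhat: np.ndarray, mask: np.ndarray) -> float:
    """RMSE restricted to the hidden (mask=True) cells."""
    x = np.asarray(x, dtype=float)
    xhat = np.asarray(xhat, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not (x.shape == xhat.shape == mask.shape):
        raise ValueError("x, xhat and mask must share one shape")
    if not mask.any():
        raise ValueError("mask has no hidden cells")
    diff = x[mask] - xhat[mask]
    return float(np.sqrt(np.mean(diff**2)))


def records_to_frame(records: list[ResultRecord]) -> pd.DataFrame:
    """Result records as a tidy DataFrame, one record per row."""
    if not records:
        raise ValueError("no records")
    return pd.DataFrame([asdict(r) for r in records])


_GROUP_KEYS = ["method", "mechanism", "rate", "n"]


def aggregate(records: list[ResultRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-condition summary across replicates.

    Returns one row per (method, mechanism, rate, n) with mean, sample
    (n-1) standard deviation, min and max of both RMSE variants.  A group
    with a single replicate reports sd = 0 by convention.  Rows are sorted
    by the group keys.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise ValueError("no records")

    def _stats(g: pd.DataFrame) -> pd.Series:
        out = {}
        for col in ("rmse_full", "rmse_masked"):
            vals = g[col].to_numpy()
            out[f"{col}_mean"] = vals.mean()
            out[f"{col}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
            out[f"{col}_min"] = vals.min()
            out[f"{col}_max"] = vals.max()
        out["n_replicates"] = len(g)
        return pd.Series(out)

    summary = (
        frame.groupby(_GROUP_KEYS, sort=True)
        .apply(_stats, include_groups=False)
        .reset_index()
        .sort_values(_GROUP_KEYS, kind="mergesort")
        .reset_index(drop=True)
    )
    summary["n_replicates"] = summary["n_replicates"].astype(int)
    return summary
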