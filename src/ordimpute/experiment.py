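"""Benchmark grid orchestration.

The full design crosses sample size (200/500/1000) x missing rate
(5/10/15%) x mechanism (MCAR/MAR) x method (7 imputers) x 10 mask
replicates.  Within one (mechanism, rate, n, replicate) cell all methods
see the *same* mask — a paired comparison — because mask seeds are a
stable hash of (base_seed, mechanism, rate, n, replicate) that excludes
the method name; imputer seeds add the method name to the tuple.  Data
matrices are drawn independently per sample size and shared across
mechanism/rate conditions, so only the masks vary within a sample size.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datasets import ScaleSpec, generate_scale_data, read_scale_csv, subsample_rows
from .evaluation import ResultRecord, aggregate, records_to_frame, rmse_full, rmse_masked, round_clip
from .impute import REGISTRY, make_imputer
from .masking import MaskResult, apply_mask, mar_mask, mcar_mask

__all__ = ["ExperimentConfig", "stable_seed", "run_condition", "run_grid"]

logger = logging.getLogger("ordimpute")

DEFAULT_METHODS = (
    "mean", "median", "em", "knn", "missforest", "autoencoder", "remasker",
)


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from an arbitrary tuple of parts.

    Stable across processes and platforms (unlike ``hash``), so reruns of
    the same configuration reproduce every mask and imputer draw.
    """
    key = "|".join(repr(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


@dataclass
class ExperimentConfig:
    """Configuration of the benchmark grid (defaults = the full design)."""

    sample_sizes: tuple[int, ...] = (200, 500, 1000)
    rates: tuple[float, ...] = (0.05, 0.10, 0.15)
    mechanisms: tuple[str, ...] = ("MCAR", "MAR")
    methods: tuple[str, ...] = DEFAULT_METHODS
    n_replicates: int = 10
    base_seed: int = 0
    data_source: str = "synthetic"  # "synthetic" | "csv"
    data_path: str | None = None
    observed_fraction: float = 0.3  # MAR pillar fraction
    paired_masks: bool = True
    category_range: tuple[int, int] = (1, 5)
    method_options: dict = field(default_factory=dict)  # per-method overrides
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if any(not 0 < r < 1 for r in self.rates):
            raise ValueError("rates must lie in (0, 1)")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 2")
        unknown = [m for m in self.methods if m not in REGISTRY]
        if unknown:
            raise ValueError(
                f"unregistered methods {unknown}; registered: {sorted(REGISTRY)}"
            )
        bad = [m for m in self.mechanisms if m not in ("MCAR", "MAR")]
        if bad:
            raise ValueError(f"unknown mechanisms {bad}")
        if self.data_source not in ("synthetic", "csv"):
            raise ValueError("data_source must be 'synthetic' or 'csv'")
        if self.data_source == "csv" and not self.data_path:
            raise ValueError("data_source='csv' requires data_path")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("sample_sizes", "rates", "mechanisms", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _make_mask(
    mechanism: str,
    data: np.ndarray,
    rate: float,
    seed: int,
    observed_fraction: float,
) -> MaskResult:
    if mechanism == "MCAR":
        return mcar_mask(data.shape[0], data.shape[1], rate, seed=seed)
    return mar_mask(
        data, rate, observed_fraction=observed_fraction, seed=seed
    )


def run_condition(
    data: np.ndarray,
    mechanism: str,
    rate: float,
    method: str,
    n_replicates: int = 10,
    base_seed: int = 0,
    observed_fraction: float = 0.3,
    paired_masks: bool = True,
    category_range: tuple[int, int] = (1, 5),
    method_options: dict | None = None,
) -> list[ResultRecord]:
    """Run one (mechanism, rate, method) cell for all mask replicates."""
    if method not in REGISTRY:
        raise ValueError(
            f"unknown method {method!r}; registered: {sorted(REGISTRY)}"
        )
    data = np.asarray(data)
    n = data.shape[0]
    lo, hi = category_range
    options = dict(method_options or {})
    records: list[ResultRecord] = []
    for r in range(1, n_replicates + 1):
        mask_key = (base_seed, "mask", mechanism, rate, n, r)
        if not paired_masks:
            mask_key = mask_key + (method,)
        mask_seed = stable_seed(*mask_key)
        mask = _make_mask(mechanism, data, rate, mask_seed, observed_fraction)
        incomplete = apply_mask(data, mask)
        imp_seed = stable_seed(base_seed, "impute", mechanism, rate, n, r, method)
        if method == "identity":
            options["ground_truth"] = data.astype(float)
        est = make_imputer(method, seed=imp_seed, **options)
        imputed = est.fit(incomplete).transform(incomplete)
        rounded = round_clip(imputed, lo, hi)
        records.append(
            ResultRecord(
                method=method,
                mechanism=mechanism,
                rate=rate,
                n=n,
                replicate=r,
                seed=imp_seed,
                rmse_full=rmse_full(data, rounded),
                rmse_masked=rmse_masked(data, rounded, mask.mask),
                achieved_rate=mask.achieved_rate,
            )
        )
    return records


def _load_data(cfg: ExperimentConfig, size: int) -> np.ndarray:
    if cfg.data_source == "csv":
        full, _ = read_scale_csv(
            cfg.data_path,
            category_min=cfg.category_range[0],
            category_max=cfg.category_range[1],
        )
        return subsample_rows(
            full, size, seed=stable_seed(cfg.base_seed, "subsample", size)
        )
    spec = ScaleSpec()
    return generate_scale_data(
        spec, size, seed=stable_seed(cfg.base_seed, "data", size)
    )


def run_grid(
    cfg: ExperimentConfig, overwrite: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the whole grid; write results.csv, summary.csv and manifest.json.

    Returns the (results, summary) frames.  Refuses to clobber an existing
    results.csv unless ``overwrite`` is set.  A single imputer failure is
    logged and skips that cell rather than aborting the grid.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_path = out / "results.csv"
    if results_path.exists() and not overwrite:
        raise FileExistsError(
            f"{results_path} exists; pass overwrite=True (--overwrite) to replace it"
        )
    if not logger.handlers:
        logging.basicConfig(level=logging.INFO, format="%(asctime)s %(message)s")
    file_handler = logging.FileHandler(out / "run.log")
    logger.addHandler(file_handler)
    records: list[ResultRecord] = []
    failures: list[str] = []
    try:
        t0 = time.time()
        for size in cfg.sample_sizes:
            data = _load_data(cfg, size)
            for mechanism in cfg.mechanisms:
                for rate in cfg.rates:
                    for method in cfg.methods:
                        tic = time.time()
                        try:
                            recs = run_condition(
                                data,
                                mechanism,
                                rate,
                                method,
                                n_replicates=cfg.n_replicates,
                                base_seed=cfg.base_seed,
                                observed_fraction=cfg.observed_fraction,
                                paired_masks=cfg.paired_masks,
                                category_range=cfg.category_range,
                                method_options=cfg.method_options.get(method),
                            )
                        except Exception as exc:  # isolate per-cell failures
                            failures.append(
                                f"{method}/{mechanism}/rate={rate}/n={size}: {exc}"
                            )
                            logger.error(
                                "FAILED %s %s rate=%.2f n=%d: %s",
                                method, mechanism, rate, size, exc,
                            )
                            continue
                        records.extend(recs)
                        mean_rmse = float(np.mean([x.rmse_full for x in recs]))
                        logger.info(
                            "%s %s rate=%.2f n=%d: mean rmse_full=%.4f (%.1fs)",
                            method, mechanism, rate, size, mean_rmse,
                            time.time() - tic,
                        )
        if not records:
            raise RuntimeError(f"every grid cell failed: {failures}")
        frame = records_to_frame(records)
        summary = aggregate(frame)
        frame.to_csv(results_path, index=False)
        summary.to_csv(out / "summary.csv", index=False)
        manifest = {
            "config": cfg.to_dict(),
            "version": __version__,
            "n_records": len(records),
            "failures": failures,
            "elapsed_seconds": round(time.time() - t0, 2),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        if failures:
            logger.warning("%d grid cell(s) failed: %s", len(failures), failures)
    finally:
        logger.removeHandler(file_handler)
        file_handler.close()
    return frame, summary
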