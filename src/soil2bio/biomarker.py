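"""Biomarker preparation: LOD substitution, creatinine adjustment,
log-transform + standardization, Tukey-fence outlier flags."""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "substitute_lod",
    "creatinine_adjust",
    "log_standardize",
    "invert_log_standardize",
    "flag_outliers",
]


def substitute_lod(raw_value, lod, below_lod):
    """Replace below-detection measurements with LOD/2 (vectorized).

    A value below the LOD whose flag is not set is left unchanged but warned
    about (inconsistent flags).
    """
    raw = np.asarray(raw_value, dtype=float)
    lod_arr = np.broadcast_to(np.asarray(lod, dtype=float), raw.shape)
    below = np.broadcast_to(np.asarray(below_lod, dtype=bool), raw.shape)
    if (lod_arr <= 0).any():
        raise ValueError("lod must be positive")
    inconsistent = (raw < lod_arr) & ~below
    if inconsistent.any():
        warnings.warn(
            f"{int(inconsistent.sum())} value(s) below LOD but not flagged below_lod"
        )
    out = np.where(below, lod_arr / 2.0, raw)
    return out if out.ndim else float(out)


def creatinine_adjust(metal_ug_per_l, creatinine_mg_per_dl):
    """Urinary dilution correction: µg analyte / L -> µg / g creatinine.

    creatinine in mg/dL; 1 mg/dL = 0.01 g/L, so
    adjusted = metal / (0.01 * creatinine). Records with nonpositive
    creatinine are excluded (NaN) with a log entry.
    """
    metal = np.asarray(metal_ug_per_l, dtype=float)
    creat = np.broadcast_to(np.asarray(creatinine_mg_per_dl, dtype=float), metal.shape)
    bad = creat <= 0
    if bad.any():
        log.info("creatinine_adjust: %d record(s) with creatinine <= 0 excluded", int(bad.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, metal / (0.01 * creat))
    return out if out.ndim else float(out)


def _is_binary(x: np.ndarray) -> bool:
    vals = set(np.unique(x[~np.isnan(x)]))
    return vals <= {0.0, 1.0}


def log_standardize(
    table: pd.DataFrame,
    outcome_column: str,
    predictor_columns: list[str],
    standardize_binary: bool = False,
):
    """Build the model-ready table: natural-log outcome, z-scored predictors.

    The outcome must be strictly positive (apply LOD substitution first).
    Binary 0/1 predictors are left unstandardized unless
    ``standardize_binary``. Zero-variance predictors are dropped with a
    warning. Returns ``(prepared, meta)``; ``meta`` records means/SDs (ddof=1)
    for exact inversion via :func:`invert_log_standardize`.
    """
    y = table[outcome_column].to_numpy(dtype=float)
    if (y <= 0).any() or np.isnan(y).any():
        raise ValueError(f"outcome {outcome_column!r} must be positive and non-missing")
    out = pd.DataFrame(index=table.index)
    out[f"log_{outcome_column}"] = np.log(y)
    meta = {"outcome": outcome_column, "predictors": {}}
    for col in predictor_columns:
        x = table[col].to_numpy(dtype=float)
        if np.nanstd(x, ddof=1) == 0 or np.isnan(np.nanstd(x, ddof=1)):
            warnings.warn(f"predictor {col!r} has zero variance: dropped")
            continue
        if _is_binary(x) and not standardize_binary:
            out[col] = x
            meta["predictors"][col] = {"mean": 0.0, "sd": 1.0, "binary": True}
            continue
        m, s = float(np.nanmean(x)), float(np.nanstd(x, ddof=1))
        if s == 0 or np.isnan(s):
            warnings.warn(f"predictor {col!r} has zero variance: dropped")
            continue
        out[col] = (x - m) / s
        meta["predictors"][col] = {"mean": m, "sd": s, "binary": False}
    return out, meta


def invert_log_standardize(prepared: pd.DataFrame, meta: dict) -> pd.DataFrame:
    """Exact inverse of :func:`log_standardize` (round-trips to ~1e-12)."""
    out = pd.DataFrame(index=prepared.index)
    out[meta["outcome"]] = np.exp(prepared[f"log_{meta['outcome']}"])
    for col, info in meta["predictors"].items():
        out[col] = prepared[col] * info["sd"] + info["mean"]
    return out


def flag_outliers(values, two_sided: bool = True) -> np.ndarray:
    """Tukey-fence outlier mask: outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Used for the outlier-removed sensitivity refits. Quartiles use linear
    interpolation between order statistics.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        raise ValueError("outlier flagging requires >= 8 values")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    mask = values > q3 + 1.5 * iqr
    if two_sided:
        mask |= values < q1 - 1.5 * iqr
    return mask
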