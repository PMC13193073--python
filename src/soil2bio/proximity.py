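"""Proximity exposure assignment: nearest sample and buffer statistics.

Each participant gets one value per proximity measure: the closest sample
within 90 m, and the mean and maximum over 90 m and 275 m buffers. A
participant with no sample within the outer buffer is flagged for exclusion
from every downstream table.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["samples_within", "assign_proximity", "PROXIMITY_METHODS"]

PROXIMITY_METHODS = ("closest", "mean90", "max90", "mean275", "max275")


def _warn_if_geographic(xy: np.ndarray) -> None:
    # projected meters expected; lon/lat magnitudes are a contract violation
    if len(xy) and np.abs(xy[:, 0]).max() <= 180 and np.abs(xy[:, 1]).max() <= 90:
        warnings.warn(
            "coordinates look geographic (|x|<=180, |y|<=90); distances assume projected meters",
            stacklevel=3,
        )


def samples_within(samples: pd.DataFrame, point, radius_m: float) -> pd.DataFrame:
    """Subset of ``samples`` within Euclidean distance ``radius_m`` of ``point``.

    Boundary samples (distance exactly equal to the radius) are included.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    xy = samples[["x", "y"]].to_numpy(dtype=float)
    _warn_if_geographic(xy)
    d = np.hypot(xy[:, 0] - point[0], xy[:, 1] - point[1])
    return samples.loc[d <= radius_m]


def assign_proximity(
    cohort: pd.DataFrame,
    samples: pd.DataFrame,
    radii: tuple[float, float] = (90.0, 275.0),
) -> pd.DataFrame:
    """Assign closest/mean/max buffer exposures for one metal.

    Returns a long table (participant_id, metal, method, value, n_support)
    plus an ``excluded`` flag per participant set when no sample lies within
    the outer radius. The closest-sample search is restricted to the inner
    radius; ties at equal distance break deterministically by lowest
    sample_id. Empty buffers yield missing values.
    """
    if samples.empty:
        raise ValueError("no soil samples provided for this metal")
    r_in, r_out = sorted(radii)
    metal = samples["metal"].iloc[0]
    sxy = samples[["x", "y"]].to_numpy(dtype=float)
    _warn_if_geographic(sxy)
    vals = samples["concentration"].to_numpy(dtype=float)
    sid = samples["sample_id"].to_numpy()
    tree = cKDTree(sxy)

    rows = []
    excluded = {}
    for _, p in cohort.iterrows():
        pid = p["participant_id"]
        home = (float(p["x"]), float(p["y"]))
        idx_out = np.asarray(tree.query_ball_point(home, r_out), dtype=int)
        d_out = np.hypot(sxy[idx_out, 0] - home[0], sxy[idx_out, 1] - home[1]) if len(idx_out) else np.array([])
        excluded[pid] = len(idx_out) == 0
        idx_in = idx_out[d_out <= r_in] if len(idx_out) else idx_out

        def emit(method, value, n):
            rows.append(
                {"participant_id": pid, "metal": metal, "method": method,
                 "value": value, "n_support": n}
            )

        if len(idx_in):
            d_in = d_out[d_out <= r_in]
            order = np.lexsort((sid[idx_in], d_in))  # distance, then sample_id
            emit("closest", vals[idx_in[order[0]]], 1)
            emit("mean90", vals[idx_in].mean(), len(idx_in))
            emit("max90", vals[idx_in].max(), len(idx_in))
        else:
            for m in ("closest", "mean90", "max90"):
                emit(m, np.nan, 0)
        if len(idx_out):
            emit("mean275", vals[idx_out].mean(), len(idx_out))
            emit("max275", vals[idx_out].max(), len(idx_out))
        else:
            emit("mean275", np.nan, 0)
            emit("max275", np.nan, 0)

    out = pd.DataFrame(rows)
    out["excluded"] = out["participant_id"].map(excluded)
    return out
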