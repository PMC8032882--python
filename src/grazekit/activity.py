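"""Grazing classification of 64-s head-tilt intervals and grazing-time
budgets paired with hourly walking distance.

The collar accelerometer reports, per 64-s interval, the proportion of
time the head-tilt angle exceeded 15 deg - i.e. the head was *up*. An
interval counts as grazing when the head was lowered at least half of
the time, so the rule inverts the sensor's proportion:
``grazing = (1 - head_up_proportion) >= threshold`` with an inclusive
tie at the default threshold 0.5.
"""

from __future__ import annotations

import datetime as dt
import warnings

import numpy as np
import pandas as pd

from .io_model import DEFAULT_TZ

__all__ = [
    "INTERVAL_SECONDS",
    "classify_interval",
    "classify",
    "grazing_minutes",
    "pair_distance_grazing",
]

INTERVAL_SECONDS = 64.0


def classify_interval(head_up_proportion: float, threshold: float = 0.5) -> bool:
    """True when the head was lowered for at least ``threshold`` of the interval."""
    if not 0.0 <= head_up_proportion <= 1.0:
        raise ValueError("head_up_proportion outside [0, 1]")
    return (1.0 - head_up_proportion) >= threshold


def classify(intervals: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Vectorised :func:`classify_interval` over an activity table.

    Input columns: ``collar_id, start, head_up_proportion``. Returns a
    copy with a boolean ``grazing`` column.
    """
    p = intervals["head_up_proportion"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("head_up_proportion outside [0, 1]")
    out = intervals.copy()
    out["grazing"] = (1.0 - p) >= threshold
    return out


def grazing_minutes(
    labels: pd.DataFrame,
    tz: dt.tzinfo = DEFAULT_TZ,
    interval_seconds: float = INTERVAL_SECONDS,
) -> pd.DataFrame:
    """Grazing time per local hour: (grazing intervals starting in the
    hour) x 64/60 minutes, capped at 60.

    Intervals belong to the hour of their start instant; no proration
    across hour boundaries (64 s << 1 h). Overlapping intervals within
    a collar indicate a corrupt export and raise.
    """
    df = labels.sort_values(["collar_id", "start"])
    starts = pd.DatetimeIndex(pd.to_datetime(df["start"], utc=True))
    for collar_id, g in df.groupby("collar_id"):
        t = pd.DatetimeIndex(pd.to_datetime(g["start"], utc=True)).asi8
        if len(t) > 1 and np.any(np.diff(t) / 1e9 < interval_seconds):
            raise ValueError(f"collar {collar_id}: overlapping activity intervals")
    local = starts.tz_convert(tz)
    out = (
        pd.DataFrame(
            {
                "collar_id": df["collar_id"].to_numpy(),
                "date": local.date,
                "hour": local.hour,
                "grazing": df["grazing"].to_numpy(),
            }
        )
        .groupby(["collar_id", "date", "hour"], sort=True)["grazing"]
        .agg(n_grazing="sum", n_intervals="size")
        .reset_index()
    )
    out["grazing_minutes"] = np.minimum(out["n_grazing"] * interval_seconds / 60.0, 60.0)
    return out


def pair_distance_grazing(
    grazing: pd.DataFrame, hourly: pd.DataFrame, require_complete: bool = True
) -> pd.DataFrame:
    """Join grazing minutes with hourly walking distance on
    (collar, date, hour).

    Hours whose distance bucket is incomplete are dropped. The joined
    table feeds the downstream grazing-time ~ distance ANCOVA, which is
    delegated to general-purpose statistics packages.
    """
    hr = hourly
    if require_complete and "complete" in hr.columns:
        hr = hr[hr["complete"]]
    merged = grazing.merge(
        hr[["collar_id", "date", "hour", "distance"]],
        on=["collar_id", "date", "hour"],
        how="inner",
    )
    if merged.empty:
        warnings.warn("no overlapping (collar, date, hour) keys", stacklevel=2)
    return merged
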