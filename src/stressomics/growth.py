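"""Doubling-time estimation from microplate OD600 time series.

The doubling time is log10(2) divided by the steepest slope of the log10-
transformed growth curve, where the slope is the ordinary-least-squares
fit over a sliding window of consecutive time points.  Points at or below
the OD floor are excluded before windowing, so early near-blank readings
cannot contribute spurious slopes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GrowthCurve", "DoublingTimeResult", "doubling_time", "compare_doubling_times"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 time series for one well."""

    times: np.ndarray  # minutes, strictly increasing
    od: np.ndarray  # OD600, >= 0
    strain: str = ""
    condition: str = ""
    well: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if times.size != od.size:
            raise ValueError("times and od must have equal length")
        if times.size < 2:
            raise ValueError("growth curve needs at least two points")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("negative OD values")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)


@dataclass(frozen=True)
class DoublingTimeResult:
    """Outcome of the steepest-slope estimator."""

    doubling_time_min: float  # NaN when non-growing
    max_slope: float  # steepest log10(OD) slope, per minute
    window_start_min: float  # left edge of the steepest window
    non_growing: bool


def _window_slopes(t: np.ndarray, logod: np.ndarray, window: int) -> np.ndarray:
    """OLS slope of logod vs t in every contiguous window of `window` points."""
    n = t.size - window + 1
    slopes = np.empty(n)
    for i in range(n):
        tw = t[i: i + window]
        yw = logod[i: i + window]
        tc = tw - tw.mean()
        slopes[i] = np.dot(tc, yw - yw.mean()) / np.dot(tc, tc)
    return slopes


def doubling_time(
    curve: GrowthCurve, window: int = 15, od_floor: float = 0.02
) -> DoublingTimeResult:
    """Doubling time (minutes) from the steepest sliding-window log-slope.

    Points with OD <= ``od_floor`` are dropped before windowing.  Raises
    when no window of ``window`` consecutive retained points exists; a
    non-positive steepest slope flags the curve as non-growing (NaN
    doubling time) rather than returning a negative estimate.

    The default window of 15 points (2.5 h at 10-min sampling) keeps the
    per-window slope standard error small relative to typical plate-reader
    noise; taking the maximum over many short noisy windows would
    otherwise systematically inflate the steepest slope and bias the
    doubling time downward.
    """
    if window < 2:
        raise ValueError("window must span at least two points")
    keep = curve.od > od_floor
    t = curve.times[keep]
    od = curve.od[keep]
    if t.size < window:
        raise ValueError(
            f"no window of {window} points above the OD floor {od_floor}"
        )
    logod = np.log10(od)
    # windows must be contiguous in the retained series; a gap from excluded
    # points only shifts the window start, matching sliding over valid data
    slopes = _window_slopes(t, logod, window)
    best = int(np.argmax(slopes))
    s = float(slopes[best])
    if s <= 0:
        return DoublingTimeResult(
            doubling_time_min=float("nan"),
            max_slope=s,
            window_start_min=float(t[best]),
            non_growing=True,
        )
    return DoublingTimeResult(
        doubling_time_min=math.log10(2.0) / s,
        max_slope=s,
        window_start_min=float(t[best]),
        non_growing=False,
    )


def compare_doubling_times(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize doubling times by strain x condition: mean, sd, n.

    Expects columns ``strain``, ``condition``, ``doubling_time_min``.
    Non-growing replicates (NaN) are excluded from n; empty cells are
    omitted with a warning in the log.  No hypothesis testing is done
    here; the replicate-level table is the export for external testing.
    """
    required = {"strain", "condition", "doubling_time_min"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for (strain, condition), sub in table.groupby(["strain", "condition"], sort=True):
        values = sub["doubling_time_min"].dropna()
        if len(values) == 0:
            logger.warning(
                "no growing replicates for strain=%r condition=%r; cell omitted",
                strain, condition,
            )
            continue
        rows.append(
            {
                "strain": strain,
                "condition": condition,
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else float("nan"),
                "n": int(len(values)),
            }
        )
    return pd.DataFrame(rows)
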