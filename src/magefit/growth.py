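"""Doubling-time estimation from kinetic OD600 growth curves.

The doubling time of a clone is computed from the steepest log-linear
stretch of its growth curve:

    t_double = c * ln(2) / m

where ``c`` is the sampling interval in minutes per time point and ``m`` is
the maximum slope of ln(OD600) per time point, found by sliding-window
least-squares regression through ``window_points`` contiguous readings
(default 8 points = 40 min at 5-min sampling).  Using the max-slope window
rather than two fixed OD thresholds makes the estimate robust to curves
that differ in lag or never reach the same final density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class GrowthEstimationError(ValueError):
    """Raised when no positive-slope growth phase exists."""


@dataclass(frozen=True)
class DoublingTimeResult:
    t_double: float  # minutes
    max_slope_m: float  # d ln(OD) per time point
    window_start_index: int
    interval_c: float  # minutes per time point


@dataclass(frozen=True)
class FitnessRecovery:
    percent_recovered: float
    t_clone: float
    t_start: float
    t_parent: float


def _window_slopes(log_od: np.ndarray, window_points: int) -> np.ndarray:
    """OLS slope of log_od against the point index for every window.

    Closed form: slope = sum((x - xbar) * y) / sum((x - xbar)^2) with
    x = 0..w-1, vectorised over all contiguous windows via a correlation.
    """
    w = window_points
    x = np.arange(w, dtype=float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    return np.correlate(log_od, xc, mode="valid") / denom


def estimate_doubling_time(
    od: np.ndarray,
    window_points: int = 8,
    interval_min: float = 5.0,
    od_floor: float = 1e-4,
) -> DoublingTimeResult:
    """Estimate doubling time (minutes) from an OD600 series.

    Parameters
    ----------
    od : array of OD600 readings at a constant interval.
    window_points : number of contiguous points per regression window.
    interval_min : minutes per time point (the ``c`` in t = c ln2 / m).
    od_floor : readings are clamped to this floor before taking logs, so
        blank-subtracted or zero readings do not produce -inf.

    Ties between equally steep windows are broken by the earliest start
    index, making the result deterministic.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 1:
        raise ValueError("expected a 1-D OD series")
    if od.size < window_points:
        raise ValueError(
            f"curve has {od.size} points; needs at least {window_points}"
        )
    if not np.isfinite(od).all():
        raise ValueError("non-finite OD reading")
    if interval_min <= 0:
        raise ValueError("interval_min must be positive")
    log_od = np.log(np.maximum(od, od_floor))
    slopes = _window_slopes(log_od, window_points)
    best = int(np.argmax(slopes))  # argmax returns the first maximum
    m = float(slopes[best])
    if m <= 0:
        raise GrowthEstimationError("non-positive max slope: no growth detected")
    return DoublingTimeResult(
        t_double=interval_min * math.log(2.0) / m,
        max_slope_m=m,
        window_start_index=best,
        interval_c=interval_min,
    )


def percent_defect_recovered(
    t_clone: float, t_start: float, t_parent: float
) -> FitnessRecovery:
    """Percent of the start strain's doubling-time defect a clone recovers.

    100 * (t_start - t_clone) / (t_start - t_parent): 0% for a clone as slow
    as the start strain, 100% at full recovery to the parent, negative if the
    clone is slower than the start strain.  The value may exceed 100.
    """
    if t_parent <= 0:
        raise ValueError("t_parent must be positive")
    if t_start <= t_parent:
        raise ValueError("defect is non-positive (t_start <= t_parent)")
    pct = 100.0 * (t_start - t_clone) / (t_start - t_parent)
    return FitnessRecovery(pct, t_clone, t_start, t_parent)


def doubling_times_for_plate(
    plate, window_points: int = 8, od_floor: float = 1e-4
):
    """Per-well doubling times for a PlateReaderTable.

    Returns a dict well -> DoublingTimeResult; wells with no detectable
    growth map to None.
    """
    out = {}
    for well, od in plate.wells.items():
        try:
            out[well] = estimate_doubling_time(
                od,
                window_points=window_points,
                interval_min=plate.interval_min,
                od_floor=od_floor,
            )
        except GrowthEstimationError:
            out[well] = None
    return out
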