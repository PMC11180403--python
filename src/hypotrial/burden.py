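"""Threshold-excursion burden metrics for MAP time series.

The trial's primary endpoint is the time-weighted average (TWA) depth of MAP
below 65 mmHg:

    AUC_<thr  [mmHg*min] = sum over samples of max(0, thr - MAP) * dt
    TWA_<thr  [mmHg]     = AUC_<thr / total surgical duration [min]

with the analogous above-threshold quantities (e.g. MAP > 130 mmHg) used to
screen for overtreatment.  Integration uses the rectangle rule on the
monitor's discrete 20-s updates — each sample stands for its following
interval and no interpolation is done at threshold crossings — so results
are bit-reproducible from the exported samples.  The comparison at the
threshold is strict ("<" below, ">" above): a sample exactly at the
threshold contributes nothing.  The denominator of the TWA is the total
surgical duration, which may exceed the monitored time.

Missing samples (NaN) are excluded from the numerators but remain inside the
total duration; series with more than 10 % missing samples are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .series import SeriesError, VitalSeries

GAP_FLAG_FRACTION = 0.10


@dataclass(frozen=True)
class ThresholdBurden:
    """Burden of one patient's MAP excursions past one threshold."""

    threshold: float
    direction: Literal["below", "above"]
    auc: float            # mmHg*min
    duration: float       # min spent past the threshold
    twa: float            # mmHg = auc / total_duration
    total_duration: float # min, the TWA denominator
    gap_flagged: bool = False


def _depths(series: VitalSeries, threshold: float, direction: str) -> np.ndarray:
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    m = np.asarray(series.map, dtype=float)
    if m.size == 0:
        raise SeriesError("empty series has no burden (distinct from zero burden)")
    if direction == "below":
        d = threshold - m
    elif direction == "above":
        d = m - threshold
    else:
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    d = np.where(np.isnan(m), 0.0, d)  # gaps contribute nothing
    return np.maximum(d, 0.0)


def auc_below(series: VitalSeries, threshold: float = 65.0) -> float:
    """Area under the threshold (mmHg*min): depth below `threshold` x time."""
    d = _depths(series, threshold, "below")
    return float(d.sum() * series.cadence_s / 60.0)


def auc_above(series: VitalSeries, threshold: float = 130.0) -> float:
    """Area above the threshold (mmHg*min), mirroring :func:`auc_below`."""
    d = _depths(series, threshold, "above")
    return float(d.sum() * series.cadence_s / 60.0)


def duration_below(series: VitalSeries, threshold: float = 65.0) -> float:
    """Minutes spent strictly below `threshold`."""
    d = _depths(series, threshold, "below")
    return float(np.count_nonzero(d > 0) * series.cadence_s / 60.0)


def duration_above(series: VitalSeries, threshold: float = 130.0) -> float:
    """Minutes spent strictly above `threshold`."""
    d = _depths(series, threshold, "above")
    return float(np.count_nonzero(d > 0) * series.cadence_s / 60.0)


def twa(auc: float, total_duration: float) -> float:
    """Time-weighted average: AUC (mmHg*min) over total duration (min)."""
    if total_duration <= 0:
        raise ValueError(f"total_duration must be positive, got {total_duration}")
    if auc < 0:
        raise ValueError(f"auc must be non-negative, got {auc}")
    return auc / total_duration


def threshold_burden(series: VitalSeries, threshold: float,
                     direction: Literal["below", "above"] = "below") -> ThresholdBurden:
    """Bundle AUC, duration and TWA for one (series, threshold, direction)."""
    if direction == "below":
        a, dur = auc_below(series, threshold), duration_below(series, threshold)
    else:
        a, dur = auc_above(series, threshold), duration_above(series, threshold)
    total = float(series.surgical_duration)
    gap_frac = float(np.isnan(series.map).mean())
    return ThresholdBurden(threshold=threshold, direction=direction, auc=a,
                           duration=dur, twa=twa(a, total), total_duration=total,
                           gap_flagged=gap_frac > GAP_FLAG_FRACTION)


def case_map_summary(series: VitalSeries) -> dict:
    """Whole-case MAP summary: mean, median, quartiles (linear interpolation,
    the convention of the standard statistical packages)."""
    m = np.asarray(series.map, dtype=float)
    m = m[~np.isnan(m)]
    if m.size == 0:
        raise SeriesError("cannot summarise an empty series")
    q1, med, q3 = np.percentile(m, [25, 50, 75])
    return {"mean": float(m.mean()), "median": float(med),
            "q1": float(q1), "q3": float(q3)}
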