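"""Doubling-time estimation from OD600 growth curves.

The exponential window of a curve is the set of readings between 0.05 and
0.75 times the maximum observed OD600 (inclusive).  log_e OD600 is fit
against time by ordinary least squares over that window, and the doubling
time is ln 2 divided by the slope.  Replicates are summarized with a mean
and a two-sided 95% t-interval.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from omiclust.errors import ValidationError
from omiclust.io_model import DoublingTimeEstimate, GrowthCurve

LN2 = float(np.log(2.0))
WINDOW_LOW = 0.05
WINDOW_HIGH = 0.75
MIN_WINDOW_POINTS = 3


def exponential_window(g: GrowthCurve) -> np.ndarray:
    """Indices with ``0.05 * max <= od600 <= 0.75 * max`` (bounds inclusive)."""
    od_max = float(g.od600.max())
    idx = np.flatnonzero(
        (g.od600 >= WINDOW_LOW * od_max) & (g.od600 <= WINDOW_HIGH * od_max)
    )
    if len(idx) < MIN_WINDOW_POINTS:
        raise ValidationError(
            f"curve {g.condition_id}/{g.replicate_id}: only {len(idx)} readings "
            f"in the exponential window; at least {MIN_WINDOW_POINTS} required"
        )
    return idx


def fit_doubling_time(g: GrowthCurve) -> tuple[float, float, int]:
    """OLS of log_e(od600) on time over the exponential window.

    Returns ``(slope_per_min, doubling_time_min, n_points_used)``.
    """
    idx = exponential_window(g)
    t = g.time_min[idx]
    y = np.log(g.od600[idx])
    slope, _ = np.polyfit(t, y, 1)
    if slope <= 0:
        raise ValidationError(
            f"curve {g.condition_id}/{g.replicate_id}: non-positive fitted "
            f"slope {slope:.3g}; no growth in the exponential window"
        )
    return float(slope), LN2 / float(slope), int(len(idx))


def summarize_replicates(
    condition_id: str,
    doubling_times_min: Sequence[float],
    slopes_per_min: Sequence[float] = (),
    n_points_used: Sequence[int] = (),
) -> DoublingTimeEstimate:
    """Mean and 95% t-interval (n-1 df) over replicate doubling times.

    A single replicate yields a flagged point estimate with no interval.
    """
    dts = tuple(float(d) for d in doubling_times_min)
    if not dts:
        raise ValidationError("at least one replicate doubling time required")
    mean = float(np.mean(dts))
    if len(dts) == 1:
        return DoublingTimeEstimate(
            condition_id=condition_id,
            per_replicate_min=dts,
            slopes_per_min=tuple(float(s) for s in slopes_per_min),
            n_points_used=tuple(int(k) for k in n_points_used),
            mean_min=mean,
            ci95_low_min=None,
            ci95_high_min=None,
            ci_undefined=True,
        )
    sem = float(np.std(dts, ddof=1) / np.sqrt(len(dts)))
    half = float(stats.t.ppf(0.975, len(dts) - 1)) * sem
    return DoublingTimeEstimate(
        condition_id=condition_id,
        per_replicate_min=dts,
        slopes_per_min=tuple(float(s) for s in slopes_per_min),
        n_points_used=tuple(int(k) for k in n_points_used),
        mean_min=mean,
        ci95_low_min=mean - half,
        ci95_high_min=mean + half,
        ci_undefined=False,
    )


def estimate_doubling_times(
    curves: Iterable[GrowthCurve],
) -> list[DoublingTimeEstimate]:
    """Fit every curve and summarize replicates per condition_id."""
    per_condition: dict[str, list[tuple[float, float, int]]] = defaultdict(list)
    for g in curves:
        per_condition[g.condition_id].append(fit_doubling_time(g))
    estimates = []
    for cond in sorted(per_condition):
        fits = per_condition[cond]
        estimates.append(
            summarize_replicates(
                cond,
                doubling_times_min=[f[1] for f in fits],
                slopes_per_min=[f[0] for f in fits],
                n_points_used=[f[2] for f in fits],
            )
        )
    return estimates
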