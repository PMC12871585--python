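"""Clonal growth estimation and dual-gate proliferation calls.

Two complementary estimators per microwell:

* ``r`` — the exponential growth rate in divisions/day, the ordinary
  least-squares slope of log2(count) against time in days.  Positive r
  means a growing clone, negative r cell death.  Zero-count timepoints
  are excluded (log undefined); at least two usable points are needed.
* ``g`` — the normalized mean count: the plain mean of the count over
  all timepoints divided by the count at t0.  g > 1 indicates growth,
  g < 1 death.  g is robust to a single miscounted frame but dilutes
  late hypergrowth, which is exactly why the two are gated jointly:
  a bright artifact can fake a steep r but rarely a sustained g.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

STATUS_OK = "ok"
STATUS_INSUFFICIENT = "insufficient_points"
STATUS_CROWDED = "crowded"


@dataclass
class GrowthEstimate:
    """Growth metrics for one microwell."""

    microwell_id: int
    r: Optional[float]  # divisions/day, signed; None unless status ok/crowded
    g: Optional[float]  # normalized mean count, dimensionless
    n_points_used: int
    residual: Optional[float]  # RMSE of the log2 fit
    status: str = STATUS_OK
    death_flag: bool = False

    def __post_init__(self) -> None:
        if self.status == STATUS_OK:
            if self.r is None or not np.isfinite(self.r):
                raise ValueError("status ok requires a finite rate")
            if self.n_points_used < 2:
                raise ValueError("status ok requires >= 2 fit points")
        if self.g is not None and self.g < 0:
            raise ValueError("g must be non-negative")


def fit_division_rate(
    counts: np.ndarray, times_hours: np.ndarray
) -> tuple[Optional[float], Optional[float], int]:
    """OLS slope of log2(count) vs time in days over nonzero timepoints.

    Returns ``(r, residual_rmse, n_points_used)``; with fewer than two
    nonzero counts the rate is undefined and ``(None, None, n)`` is
    returned.  Trailing zeros after a nonzero start simply drop out of
    the fit, so a dying clone still gets a (negative) rate from its
    observed segment.
    """
    counts = np.asarray(counts, dtype=float)
    times_hours = np.asarray(times_hours, dtype=float)
    if counts.shape != times_hours.shape:
        raise ValueError("counts and times must align")
    usable = counts >= 1
    n_used = int(usable.sum())
    if n_used < 2:
        return None, None, n_used
    t_days = times_hours[usable] / 24.0
    y = np.log2(counts[usable])
    slope, intercept = np.polyfit(t_days, y, 1)
    resid = float(np.sqrt(np.mean((y - (slope * t_days + intercept)) ** 2)))
    return float(slope), resid, n_used


def normalized_mean_count(counts: np.ndarray) -> Optional[float]:
    """Mean count over all timepoints (t0 included) divided by count(t0).

    Undefined (None) when the microwell is empty at t0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts[0] < 1:
        return None
    return float(counts.mean() / counts[0])


def estimate_growth(
    counts: np.ndarray,
    times_hours: np.ndarray,
    microwell_id: int = -1,
    crowded: bool = False,
    include_t0_in_mean: bool = True,
) -> GrowthEstimate:
    """Both estimators plus status for one trajectory."""
    counts = np.asarray(counts, dtype=float)
    r, resid, n_used = fit_division_rate(counts, times_hours)
    g_counts = counts if include_t0_in_mean else counts[1:]
    g = (
        float(g_counts.mean() / counts[0]) if counts[0] >= 1 and len(g_counts) else None
    )
    if r is None:
        status = STATUS_INSUFFICIENT
    elif crowded:
        status = STATUS_CROWDED
    else:
        status = STATUS_OK
    return GrowthEstimate(
        microwell_id=microwell_id,
        r=r,
        g=g,
        n_points_used=n_used,
        residual=resid,
        status=status,
        death_flag=bool(r is not None and r < 0),
    )


def classify_proliferative(
    estimates: list[GrowthEstimate], r_min: float = 0.25, g_min: float = 1.2
) -> tuple[np.ndarray, list[str]]:
    """Dual gate: proliferative iff r >= r_min AND g >= g_min.

    Requiring both suppresses artifact-driven calls where one estimator
    spikes.  Undefined estimates classify False with a reason code;
    reasons are '' for cleanly gated microwells.
    """
    flags = np.zeros(len(estimates), dtype=bool)
    reasons = []
    for k, est in enumerate(estimates):
        if est.r is None or est.g is None:
            reasons.append(est.status if est.r is None else "g_undefined")
            continue
        flags[k] = est.r >= r_min and est.g >= g_min
        reasons.append("")
    return flags, reasons


def viable_clone_fraction(
    trajectories: np.ndarray, occupancy_t0: np.ndarray
) -> float:
    """Fraction of single-cell microwells whose occupant divided at least once.

    Numerator: single-cell microwells reaching a count of >= 2 at any
    timepoint; denominator: all single-cell microwells.
    """
    trajectories = np.asarray(trajectories)
    occupancy_t0 = np.asarray(occupancy_t0)
    singles = occupancy_t0 == 1
    if not singles.any():
        raise ValueError("no single-cell microwells at t0")
    divided = trajectories[singles].max(axis=1) >= 2
    return float(divided.mean())
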