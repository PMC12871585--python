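"""Secretion-ring quantification and positive calling.

Cytokine secreted inside a microwell is captured by antibodies on the
conical walls and continuously labelled by a soluble detection
antibody, so a secreting clone paints an annular "secretion ring" that
brightens over time.  Two statistics per microwell and timepoint:

* relative signal ``S(t) = I(t) - I(t0)`` where I is the mean intensity
  of a wall annulus — differencing removes the static background, so S
  is invariant to any global additive offset;
* rotational symmetry ``sigma_sym`` — the coefficient of variation of
  the annulus intensity across equal angular sectors.  A genuine ring
  is rotationally uniform (sigma_sym ~ 0); cytokine captured from an
  adjacent microwell arrives as a one-sided arc with high sector CV,
  which is the false-positive mode the symmetry gate rejects.

A microwell is called positive at the first timepoint where S clears an
intensity threshold AND sigma_sym stays below the symmetry threshold.
The default intensity threshold is control-derived: mean + 5 SD of S
over occupied-but-unstimulated control microwells at the matched
timepoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

INF_SENTINEL = float("inf")


class AnnulusSpec(BaseModel):
    """Wall band between the cell zone and the rim, as fractions of pitch."""

    inner_fraction: float = Field(0.25, gt=0.0)  # 0.5 * bottom_diam / pitch
    outer_fraction: float = Field(0.475, le=0.5)  # 0.95 * (pitch/2) / pitch
    n_sectors: int = Field(8, ge=4)

    @model_validator(mode="after")
    def _ordered(self) -> "AnnulusSpec":
        if not self.inner_fraction < self.outer_fraction:
            raise ValueError("inner fraction must be below outer fraction")
        return self

    def radii_px(self, pitch_px: float) -> tuple[float, float]:
        return self.inner_fraction * pitch_px, self.outer_fraction * pitch_px


@dataclass
class SecretionSignal:
    """Ring time series and gate outcome for one microwell."""

    microwell_id: int
    times_hours: np.ndarray
    ring_intensity: np.ndarray  # I(t)
    symmetry: np.ndarray  # sigma_sym(t)
    positive: bool = False
    first_positive_t: Optional[int] = None  # timepoint index
    well: str = "A1"
    extra: dict = field(default_factory=dict)

    @property
    def relative(self) -> np.ndarray:
        """S(t) = I(t) - I(t0); S(t0) is exactly 0."""
        return self.ring_intensity - self.ring_intensity[0]


def _annulus_masks(shape: tuple[int, int], pitch_px: float, spec: AnnulusSpec):
    inner, outer = spec.radii_px(pitch_px)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    dist = np.hypot(yy - cy, xx - cx)
    ring = (dist >= inner) & (dist <= outer)
    if not ring.any():
        raise ValueError(
            f"annulus [{inner:.1f}, {outer:.1f}] px is empty on a "
            f"{shape} crop at this pixel size"
        )
    ang = np.arctan2(yy - cy, xx - cx)  # [-pi, pi]
    sector = ((ang + math.pi) / (2 * math.pi) * spec.n_sectors).astype(int)
    sector = np.clip(sector, 0, spec.n_sectors - 1)
    return ring, sector


def ring_intensity(
    cyto_crop: np.ndarray, annulus: AnnulusSpec | None = None, pitch_px: float | None = None
) -> float:
    """Mean intensity over the wall annulus of a centered crop."""
    crop = np.asarray(cyto_crop, dtype=float)
    annulus = annulus or AnnulusSpec()
    pitch_px = pitch_px if pitch_px is not None else float(min(crop.shape))
    ring, _ = _annulus_masks(crop.shape, pitch_px, annulus)
    return float(crop[ring].mean())


def relative_signal(intensity_series: Sequence[float], t_x: int) -> float:
    """S(t_x) = I(t_x) - I(t_0)."""
    series = np.asarray(intensity_series, dtype=float)
    if not -len(series) <= t_x < len(series):
        raise IndexError(f"timepoint {t_x} outside series of length {len(series)}")
    return float(series[t_x] - series[0])


def symmetry_score(
    cyto_crop: np.ndarray, annulus: AnnulusSpec | None = None, pitch_px: float | None = None
) -> float:
    """Sector coefficient of variation of the annulus intensity.

    The annulus is split into ``n_sectors`` equal angular sectors;
    sigma_sym = SD(sector means) / mean(sector means).  A non-positive
    mean (nothing above background) returns the +inf sentinel so that
    flat crops can never pass a "<= threshold" symmetry gate by
    accident.  Invariant to rotation by multiples of the sector angle
    and to global intensity scaling.
    """
    crop = np.asarray(cyto_crop, dtype=float)
    annulus = annulus or AnnulusSpec()
    pitch_px = pitch_px if pitch_px is not None else float(min(crop.shape))
    ring, sector = _annulus_masks(crop.shape, pitch_px, annulus)
    means = np.array(
        [crop[ring & (sector == s)].mean() for s in range(annulus.n_sectors)]
    )
    mean = means.mean()
    if mean <= 0:
        return INF_SENTINEL
    return float(means.std() / mean)


def derive_threshold_from_controls(control_S: np.ndarray, k_sd: float = 5.0):
    """Intensity threshold(s) from unstimulated control microwells.

    ``control_S`` is (n_controls, T) relative signals; returns the per-
    timepoint threshold mean + k_sd * SD.  This is the default when no
    absolute threshold is configured.
    """
    control_S = np.atleast_2d(np.asarray(control_S, dtype=float))
    return control_S.mean(axis=0) + k_sd * control_S.std(axis=0)


def call_positive(
    signal: SecretionSignal,
    S_threshold,
    sym_threshold: float = 0.5,
    t_window: tuple[int, int] | None = None,
) -> tuple[bool, Optional[int]]:
    """Intensity + symmetry gate over a time window.

    Positive iff at some timepoint in the window S(t) >= S_threshold(t)
    and sigma_sym(t) <= sym_threshold; the first such timepoint is
    recorded.  ``S_threshold`` may be a scalar or a per-timepoint array
    (e.g. from :func:`derive_threshold_from_controls`).  The outcome is
    stored on the signal and returned.
    """
    if S_threshold is None:
        raise ValueError(
            "no intensity threshold: provide an absolute S_threshold or "
            "derive one from control microwells"
        )
    S = signal.relative
    thr = np.broadcast_to(np.asarray(S_threshold, dtype=float), S.shape)
    lo, hi = (1, len(S)) if t_window is None else t_window
    for t in range(max(lo, 0), min(hi, len(S))):
        if S[t] >= thr[t] and signal.symmetry[t] <= sym_threshold:
            signal.positive, signal.first_positive_t = True, t
            return True, t
    signal.positive, signal.first_positive_t = False, None
    return False, None


def measure_signal(
    crops_by_t: Sequence[np.ndarray],
    times_hours: np.ndarray,
    microwell_id: int = -1,
    annulus: AnnulusSpec | None = None,
    pitch_px: float | None = None,
    well: str = "A1",
) -> SecretionSignal:
    """Ring intensity and symmetry series for one microwell.

    Symmetry at t is computed on the ``crop(t) - crop(t0)`` difference
    image, so the static well background does not dilute the sector CV
    of an accumulated arc; at t0 the (all-zero) difference yields the
    +inf sentinel, which is fine since calling starts at t >= 1.
    """
    annulus = annulus or AnnulusSpec()
    crops = [np.asarray(c, dtype=float) for c in crops_by_t]
    intensities = np.array([ring_intensity(c, annulus, pitch_px) for c in crops])
    sym = np.array(
        [
            symmetry_score(c - crops[0], annulus, pitch_px)
            for c in crops
        ]
    )
    return SecretionSignal(
        microwell_id=microwell_id,
        times_hours=np.asarray(times_hours, dtype=float),
        ring_intensity=intensities,
        symmetry=sym,
        well=well,
    )


def positive_counts_over_time(
    signals: Sequence[SecretionSignal], grouping: str = "well"
) -> pd.DataFrame:
    """Cumulative positive-microwell counts per group per timepoint.

    Mirrors the per-well bar charts of accumulated-cytokine microwells:
    a microwell contributes to every timepoint at or after its first
    positive call.
    """
    if not signals:
        return pd.DataFrame(columns=[grouping, "timepoint", "n_positive"])
    n_t = len(signals[0].times_hours)
    rows = []
    groups = sorted({getattr(s, grouping) for s in signals})
    for grp in groups:
        onsets = [
            s.first_positive_t
            for s in signals
            if getattr(s, grouping) == grp and s.positive
        ]
        for t in range(n_t):
            rows.append(
                {
                    grouping: grp,
                    "timepoint": t,
                    "n_positive": sum(1 for o in onsets if o <= t),
                }
            )
    return pd.DataFrame(rows)
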