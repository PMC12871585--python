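"""Microwell-lattice detection, registration and cropping.

The microwell array is a strongly periodic lattice of dark rings in the
brightfield channel.  Detection is classical: a matched smoothing of the
inverted frame turns each ring into a peak, local-extrema picking finds
candidate centers, and a robust pitch/angle fit assigns stable row-major
integer IDs.  A pluggable detector hook allows a learned model to
replace the peak picker without touching the rest of the pipeline.

Registration estimates one global integer-pixel shift per timepoint
(stage drift is mechanical, so the whole frame moves together); IDs are
assigned once at t0 and never re-identified.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional
import warnings

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max


class NoLatticeError(ValueError):
    """Fewer than 4 credible lattice sites found."""


class CalibrationError(ValueError):
    """Detected pitch disagrees with the configured layout by >20%."""


class PlateLayout(BaseModel):
    """Plate, well and microwell-lattice geometry."""

    wells_rows: int = 8
    wells_cols: int = 12
    microwells_per_well: int = 3958  # ~380,000 / 96
    accessible_area_fraction: float = Field(0.75, gt=0.0, le=1.0)
    pitch_um: float = Field(130.0, gt=0.0)
    bottom_diam_um: float = 65.0
    pixel_size_um: float = Field(2.0, gt=0.0)

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.pixel_size_um

    @property
    def bottom_radius_px(self) -> float:
        return 0.5 * self.bottom_diam_um / self.pixel_size_um


@dataclass
class MicrowellGrid:
    """Detected (or ground-truth) microwell lattice.

    Centers are t0 positions in (y, x) pixels; ``shifts`` holds the
    global per-timepoint drift with ``shifts[0] == (0, 0)``.  IDs are
    stable integers assigned row-major from the top-left at detection
    time and never reassigned.
    """

    ids: np.ndarray
    centers_t0: np.ndarray  # (n, 2) float, (y, x)
    lattice_rows: np.ndarray
    lattice_cols: np.ndarray
    shifts: np.ndarray  # (T, 2) float, (dy, dx)
    pitch_px: float
    pixel_size_um: float
    accessible: np.ndarray = None
    detection_score: np.ndarray = None
    rotation_deg: float = 0.0
    ref_frame: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.centers_t0 = np.asarray(self.centers_t0, dtype=float)
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("microwell ids must be unique")
        if self.accessible is None:
            self.accessible = np.ones(len(self.ids), dtype=bool)
        if self.detection_score is None:
            self.detection_score = np.ones(len(self.ids))
        self.shifts = np.atleast_2d(np.asarray(self.shifts, dtype=float))
        if len(self.shifts) and not np.allclose(self.shifts[0], 0):
            raise ValueError("shift at t0 must be (0, 0)")
        self._index = {int(i): k for k, i in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def row_of(self, microwell_id: int) -> int:
        try:
            return self._index[int(microwell_id)]
        except KeyError:
            raise KeyError(f"unknown microwell id {microwell_id}") from None

    def center_at(self, microwell_id: int, t: int = 0) -> np.ndarray:
        """Center of a microwell at timepoint ``t`` (t0 center + drift)."""
        k = self.row_of(microwell_id)
        if not 0 <= t < len(self.shifts):
            raise IndexError(
                f"timepoint {t} has no registered shift (have {len(self.shifts)})"
            )
        return self.centers_t0[k] + self.shifts[t]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "microwell_id": self.ids,
                "row": self.lattice_rows,
                "col": self.lattice_cols,
                "y": self.centers_t0[:, 0],
                "x": self.centers_t0[:, 1],
                "accessible": self.accessible,
                "detection_score": self.detection_score,
            }
        )

    def save(self, csv_path, json_path=None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(
                json.dumps(
                    {
                        "pitch_px": self.pitch_px,
                        "pixel_size_um": self.pixel_size_um,
                        "rotation_deg": self.rotation_deg,
                        "shifts": self.shifts.tolist(),
                    },
                    indent=2,
                )
            )

    @classmethod
    def load(cls, csv_path, json_path) -> "MicrowellGrid":
        df = pd.read_csv(csv_path)
        meta = json.loads(Path(json_path).read_text())
        return cls(
            ids=df["microwell_id"].to_numpy(),
            centers_t0=df[["y", "x"]].to_numpy(),
            lattice_rows=df["row"].to_numpy(),
            lattice_cols=df["col"].to_numpy(),
            shifts=np.asarray(meta["shifts"]),
            pitch_px=meta["pitch_px"],
            pixel_size_um=meta["pixel_size_um"],
            accessible=df["accessible"].to_numpy(dtype=bool),
            detection_score=df["detection_score"].to_numpy(),
            rotation_deg=meta.get("rotation_deg", 0.0),
        )


# ---------------------------------------------------------------------------
# detection


def _peak_candidates(bf_frame: np.ndarray, layout: PlateLayout) -> tuple[np.ndarray, np.ndarray]:
    """Default classical detector: matched smoothing + local maxima.

    Returns (n, 2) float sub-pixel centers and their response scores.
    """
    frame = np.asarray(bf_frame, dtype=float)
    inv = np.median(frame) - frame  # wells are dark on bright background
    # sigma must exceed ring_radius/sqrt(2), else the smoothed ring keeps a
    # crater ridge instead of a single central peak
    resp = ndimage.gaussian_filter(inv, sigma=max(1.0, layout.bottom_radius_px))
    med = float(np.median(resp))
    span = float(resp.max() - med)
    # a flat frame has no ring contrast at all: nothing credible to pick
    if span <= 1e-9 * (abs(med) + 1.0):
        return np.zeros((0, 2)), np.zeros(0)
    floor = med + 0.3 * span
    coords = peak_local_max(
        resp,
        min_distance=max(2, int(0.6 * layout.pitch_px)),
        threshold_abs=floor,
        exclude_border=int(layout.bottom_radius_px),
    )
    if len(coords) == 0:
        return np.zeros((0, 2)), np.zeros(0)
    # sub-pixel refinement: centroid of the inverted intensity restricted to
    # the wall-ring band, so cells at the well bottom cannot bias the center
    refined = np.empty((len(coords), 2))
    r_ring = layout.bottom_radius_px
    band = max(2.0, 0.25 * r_ring)
    win = int(math.ceil(r_ring + band)) + 1
    pos = np.clip(inv, 0, None)
    for k, (py, px) in enumerate(coords):
        cy, cx = float(py), float(px)
        for _ in range(3):
            y0, y1 = max(int(cy) - win, 0), min(int(cy) + win + 1, inv.shape[0])
            x0, x1 = max(int(cx) - win, 0), min(int(cx) + win + 1, inv.shape[1])
            gy, gx = np.mgrid[y0:y1, x0:x1]
            dist = np.hypot(gy - cy, gx - cx)
            w = pos[y0:y1, x0:x1] * (np.abs(dist - r_ring) <= band)
            total = w.sum()
            if total <= 0:
                break
            cy, cx = (gy * w).sum() / total, (gx * w).sum() / total
        refined[k] = (cy, cx)
    scores = resp[tuple(coords.T)]
    return refined, scores


def detect_grid(
    bf_frame: np.ndarray,
    layout: PlateLayout,
    detector: Callable[[np.ndarray, PlateLayout], tuple[np.ndarray, np.ndarray]] | None = None,
) -> MicrowellGrid:
    """Detect the microwell lattice in a t0 brightfield frame.

    ``detector`` maps (frame, layout) to candidate centers + scores; the
    default is the classical matched-filter peak picker.  Candidates are
    then fit to a square lattice (robust pitch estimate from nearest-
    neighbour spacing, rotation from neighbour angles folded to the
    nearest axis) and IDs assigned row-major after rotation correction.
    """
    find = detector or _peak_candidates
    centers, scores = find(bf_frame, layout)
    if len(centers) < 4:
        raise NoLatticeError(
            f"no lattice found: only {len(centers)} credible sites detected"
        )

    tree = cKDTree(centers)
    nn_dist, nn_idx = tree.query(centers, k=2)
    est_pitch = float(np.median(nn_dist[:, 1]))
    if abs(est_pitch - layout.pitch_px) / layout.pitch_px > 0.20:
        raise CalibrationError(
            f"detected pitch {est_pitch:.1f} px differs from configured "
            f"{layout.pitch_px:.1f} px by more than 20%"
        )

    # rotation: nearest-neighbour displacement angles folded onto [-45, 45)
    vec = centers[nn_idx[:, 1]] - centers
    ang = np.degrees(np.arctan2(vec[:, 0], vec[:, 1]))
    folded = (ang + 45.0) % 90.0 - 45.0
    theta = float(np.median(folded))
    if abs(theta) > 5.0:
        theta = 0.0  # out of supported range; fall back to axis-aligned

    th = math.radians(theta)
    rot = np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])
    origin = centers.min(axis=0)
    lattice_coords = (centers - origin) @ rot.T / est_pitch
    rows = np.round(lattice_coords[:, 0]).astype(np.int64)
    cols = np.round(lattice_coords[:, 1]).astype(np.int64)
    rows -= rows.min()
    cols -= cols.min()

    # deduplicate lattice cells (keep strongest response), drop edge-clipped
    order = np.argsort(-scores)
    seen: dict[tuple[int, int], int] = {}
    keep = []
    margin = layout.bottom_radius_px
    hmax, wmax = np.asarray(bf_frame).shape
    for k in order:
        cell = (int(rows[k]), int(cols[k]))
        y, x = centers[k]
        if cell in seen:
            continue
        if not (margin <= y <= hmax - margin and margin <= x <= wmax - margin):
            continue
        seen[cell] = k
        keep.append(k)
    keep = sorted(keep, key=lambda k: (rows[k], cols[k]))
    keep = np.asarray(keep, dtype=int)

    return MicrowellGrid(
        ids=np.arange(len(keep), dtype=np.int64),
        centers_t0=centers[keep],
        lattice_rows=rows[keep],
        lattice_cols=cols[keep],
        shifts=np.zeros((1, 2)),
        pitch_px=est_pitch,
        pixel_size_um=layout.pixel_size_um,
        detection_score=scores[keep],
        rotation_deg=theta,
        ref_frame=np.asarray(bf_frame, dtype=float),
    )


# ---------------------------------------------------------------------------
# registration


def register_timepoint(
    grid: MicrowellGrid,
    bf_frame_t: np.ndarray,
    max_shift: int | None = None,
    corr_floor: float = 0.1,
    append: bool = True,
) -> tuple[int, int]:
    """Global integer-pixel drift of ``bf_frame_t`` relative to t0.

    Maximizes the FFT cross-correlation between the stored t0 reference
    and the new frame within a +/-``max_shift`` window (default just
    under half a pitch, to rule out lattice-period aliasing).  A
    normalized correlation peak below ``corr_floor`` triggers a warning
    and a zero shift.  The shift is appended to ``grid.shifts`` so that
    ``center_at(id, t)`` resolves for the new timepoint.
    """
    if grid.ref_frame is None:
        raise ValueError("grid carries no t0 reference frame; detect first")
    if max_shift is None:
        max_shift = max(1, int(grid.pitch_px / 2) - 1)
    a = grid.ref_frame - grid.ref_frame.mean()
    b = np.asarray(bf_frame_t, dtype=float)
    b = b - b.mean()
    if a.shape != b.shape:
        raise ValueError(f"frame shape {b.shape} != reference {a.shape}")
    corr = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    # corr[dy, dx] ~ sum a(y, x) * b(y + dy, x + dx) with periodic indexing
    window = np.full(corr.shape, -np.inf)
    idx = np.arange(-max_shift, max_shift + 1)
    window[np.ix_(idx, idx)] = corr[np.ix_(idx, idx)]
    peak = np.unravel_index(np.argmax(window), corr.shape)
    dy = int(peak[0] if peak[0] <= corr.shape[0] // 2 else peak[0] - corr.shape[0])
    dx = int(peak[1] if peak[1] <= corr.shape[1] // 2 else peak[1] - corr.shape[1])
    norm = math.sqrt((a**2).sum() * (b**2).sum()) + 1e-12
    if corr[peak] / norm < corr_floor:
        warnings.warn(
            f"correlation peak {corr[peak] / norm:.3f} below floor "
            f"{corr_floor}; assuming zero drift",
            stacklevel=2,
        )
        dy, dx = 0, 0
    if append:
        grid.shifts = np.vstack([grid.shifts, [float(dy), float(dx)]])
    return dy, dx


# ---------------------------------------------------------------------------
# cropping and accessibility


def crop_microwell(stack, grid: MicrowellGrid, microwell_id: int, t: int, channel) -> np.ndarray:
    """Square per-microwell crop of side ceil(pitch) px at timepoint ``t``.

    The crop follows the registered drift, so the same microwell content
    stays centered across timepoints.
    """
    side = int(math.ceil(grid.pitch_px))
    half = side // 2
    cy, cx = np.round(grid.center_at(microwell_id, t)).astype(int)
    frame = stack.frame(t, channel)
    if not (half <= cy <= frame.shape[0] - half and half <= cx <= frame.shape[1] - half):
        raise ValueError(
            f"microwell {microwell_id} crop at t={t} would clip the frame edge"
        )
    return frame[cy - half:cy - half + side, cx - half:cx - half + side]


def accessible_mask(grid: MicrowellGrid, layout: PlateLayout) -> np.ndarray:
    """Flag microwells the picker tip can reach.

    The well footprint is the bounding circle of the detected centers;
    a site is accessible iff it lies inside the concentric circle
    enclosing ``accessible_area_fraction`` of the footprint area, i.e.
    within radius fraction sqrt(fraction) (~0.866 for the central 75%).
    The flags are stored on the grid and returned.
    """
    c = grid.centers_t0.mean(axis=0)
    radii = np.linalg.norm(grid.centers_t0 - c, axis=1)
    footprint_r = radii.max()
    mask = radii <= math.sqrt(layout.accessible_area_fraction) * footprint_r + 1e-9
    grid.accessible = mask
    return mask
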