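"""Per-crop cell detection, fluorescence quantification and classification.

Cells sediment to the conical well bottom, so segmentation is restricted
to the central bottom zone of each crop — this also keeps the dark wall
ring of the microwell itself out of the blob detector.  The pipeline is
classical (background flattening, robust threshold, watershed split on
the distance transform, size gate); a ``detector`` hook mirrors
gridmap's so a learned instance-segmentation model can be plugged in.

The brightfield mask of each cell is the template for quantifying its
mean fluorescence in every other channel, which is what marker-based
classification (e.g. CD4/CD8, GFP/mCherry) consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

#: above this many detected objects a crop is reported as crowded and the
#: count treated as saturating (dense colonies merge; see package docs)
CROWDED_LIMIT = 50


@dataclass
class CellRecord:
    """One detected cell in one microwell crop at one timepoint."""

    microwell_id: int
    timepoint: int
    cell_index: int
    centroid: tuple[float, float]  # (y, x) px within the crop
    equivalent_diameter_um: float
    channel_means: dict[str, float] = field(default_factory=dict)
    labels: dict[str, bool] = field(default_factory=dict)
    mask_coords: tuple = field(default=None, repr=False)  # (rr, cc) arrays

    def __post_init__(self) -> None:
        if self.equivalent_diameter_um <= 0:
            raise ValueError("equivalent diameter must be positive")


@dataclass
class MarkerRule:
    """Threshold rule on one fluorescence channel, e.g. GFP+ or mCherry-."""

    channel: str
    threshold: float
    polarity: str = "+"  # "+" keeps cells above threshold, "-" below
    label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")
        if not self.label:
            self.label = f"{self.channel}{self.polarity}"

    def applies(self, mean_intensity: float) -> bool:
        return (
            mean_intensity >= self.threshold
            if self.polarity == "+"
            else mean_intensity < self.threshold
        )


def default_marker_threshold(background_values: np.ndarray) -> float:
    """Per-plate default threshold: background median + 5 * MAD."""
    bg = np.asarray(background_values, dtype=float)
    mad = np.median(np.abs(bg - np.median(bg)))
    return float(np.median(bg) + 5.0 * 1.4826 * mad)


def _segment(
    bf_crop: np.ndarray,
    pixel_size_um: float,
    min_diam_um: float,
    max_diam_um: float,
    bottom_zone_radius_px: float | None,
    k_mad: float,
) -> np.ndarray:
    """Label image of candidate cells (dark blobs) in the bottom zone."""
    crop = np.asarray(bf_crop, dtype=float)
    inv = np.median(crop) - crop  # cells absorb light: dark on bright
    if bottom_zone_radius_px is None:
        # cells sediment to the conical bottom; with the standard geometry
        # (bottom diameter = pitch/2) the wall ring sits at 0.25 * crop side,
        # so the default zone stays just inside it
        bottom_zone_radius_px = 0.22 * min(crop.shape)
    yy, xx = np.mgrid[: crop.shape[0], : crop.shape[1]]
    cy, cx = (crop.shape[0] - 1) / 2, (crop.shape[1] - 1) / 2
    zone = np.hypot(yy - cy, xx - cx) <= bottom_zone_radius_px

    mad = np.median(np.abs(inv - np.median(inv)))
    fg = zone & (inv > k_mad * 1.4826 * mad + 1e-9)
    if not fg.any():
        return np.zeros(crop.shape, dtype=np.int32)

    # watershed split of touching blobs on the distance transform
    min_r_px = 0.5 * min_diam_um / pixel_size_um
    dist = ndimage.distance_transform_edt(fg)
    peaks = peak_local_max(
        dist,
        min_distance=max(2, int(round(min_r_px))),
        labels=fg,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return np.zeros(crop.shape, dtype=np.int32)
    markers = np.zeros(crop.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-dist, markers, mask=fg).astype(np.int32)


def count_cells(
    bf_crop: np.ndarray,
    min_diam_um: float = 5.0,
    max_diam_um: float = 20.0,
    pixel_size_um: float = 2.0,
    microwell_id: int = -1,
    timepoint: int = 0,
    bottom_zone_radius_px: float | None = None,
    k_mad: float = 5.0,
    detector=None,
) -> list[CellRecord]:
    """Detect and size-gate cells in a brightfield crop.

    Objects with equivalent diameter outside [min_diam_um, max_diam_um]
    are discarded — the lower bound removes debris, the upper bound
    removes artifacts (the field's usual ">20 um is not a cell" rule).
    Deterministic given the pixels; an empty microwell yields ``[]``.
    """
    segment = detector or _segment
    labels = segment(
        bf_crop, pixel_size_um, min_diam_um, max_diam_um, bottom_zone_radius_px, k_mad
    )
    records: list[CellRecord] = []
    for prop in regionprops(labels):
        diam_um = prop.equivalent_diameter_area * pixel_size_um
        if not (min_diam_um <= diam_um <= max_diam_um):
            continue
        rr, cc = np.nonzero(labels == prop.label)
        records.append(
            CellRecord(
                microwell_id=microwell_id,
                timepoint=timepoint,
                cell_index=len(records),
                centroid=tuple(float(v) for v in prop.centroid),
                equivalent_diameter_um=float(diam_um),
                mask_coords=(rr, cc),
            )
        )
    return records


def cell_intensities(
    cell_records: list[CellRecord], fluor_crops: dict[str, np.ndarray]
) -> list[CellRecord]:
    """Mean fluorescence of each cell's brightfield mask, per channel.

    The brightfield mask is the template; the crop-local background
    (median over pixels outside every mask) is subtracted, which is
    robust to secretion-ring fluorescence at the crop edges.
    """
    if not cell_records:
        return cell_records
    shape = None
    for rec in cell_records:
        if rec.mask_coords is None:
            raise ValueError("cell records carry no masks; run count_cells first")
    for name, crop in fluor_crops.items():
        crop = np.asarray(crop, dtype=float)
        if shape is None:
            shape = crop.shape
        elif crop.shape != shape:
            raise ValueError(
                f"channel {name!r} crop shape {crop.shape} != {shape}"
            )
        in_mask = np.zeros(crop.shape, dtype=bool)
        for rec in cell_records:
            in_mask[rec.mask_coords] = True
        background = float(np.median(crop[~in_mask])) if (~in_mask).any() else 0.0
        for rec in cell_records:
            rec.channel_means[name] = float(crop[rec.mask_coords].mean() - background)
    return cell_records


def classify_cells(
    cell_records: list[CellRecord], rules: list[MarkerRule]
) -> list[CellRecord]:
    """Apply marker rules; each rule contributes one boolean label.

    Composite phenotypes (GFP+/mCherry-) are conjunctions of the
    individual rule labels, exposed via :func:`composite_label`.
    """
    for rec in cell_records:
        for rule in rules:
            if rule.channel not in rec.channel_means:
                raise KeyError(
                    f"rule {rule.label!r} references channel {rule.channel!r} "
                    f"absent from intensities {sorted(rec.channel_means)}"
                )
            rec.labels[rule.label] = rule.applies(rec.channel_means[rule.channel])
    return cell_records


def composite_label(record: CellRecord, labels: list[str]) -> bool:
    """Conjunction of named rule labels, e.g. ['GFP+', 'mCherry-']."""
    return all(record.labels[lbl] for lbl in labels)


def crop_mean_intensity(crop: np.ndarray) -> float:
    """Arithmetic mean of all crop pixels (junk/autofluorescence screen)."""
    return float(np.asarray(crop, dtype=float).mean())


def is_crowded(records: list[CellRecord], limit: int = CROWDED_LIMIT) -> bool:
    """True when the count saturates the detector (dense colony)."""
    return len(records) >= limit
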