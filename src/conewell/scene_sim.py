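"""Synthetic microwell-array scenes with complete ground truth.

Emulates the imaging output of a conical-microwell live-cell platform:
a brightfield channel in which each microwell appears as a dark ring on
a bright background with cells as dark blobs at the well bottom,
optional surface-marker fluorescence channels, and a cytokine channel
in which secretion-positive microwells accumulate an annular "secretion
ring" linearly over time.  Cross-talk victims — microwells that capture
cytokine diffusing from a secreting neighbour — receive a one-sided arc
carrying the same total signal, the false-positive mode the rotational
symmetry gate exists to reject.

Everything is seeded: one integer seed drives a single generator per
scene, so identical configs give bit-identical stacks and truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional
import json

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .ngff_io import FrameStack
from .gridmap import MicrowellGrid

# ---------------------------------------------------------------------------
# configuration


class GrowthModel(BaseModel):
    """Log2-rate distribution for per-microwell clonal growth.

    Rates are divisions/day; the growing population is lognormal around
    ``median_rate_div_per_day`` and a ``death_fraction`` of occupied
    microwells instead receives a negative (decay) rate.
    """

    median_rate_div_per_day: float = 0.8
    sigma: float = 0.4
    death_fraction: float = Field(0.05, ge=0.0, le=1.0)


class SecretionModel(BaseModel):
    """Cytokine-ring rendering parameters.

    ``accumulation_rate`` is intensity units gained per hour by the wall
    annulus of a secretion-positive microwell.  ``cross_talk_fraction``
    of co-cultures become victims: an arc covering ``arc_fraction`` of
    the ring circumference carries the same *total* signal (so it passes
    a pure intensity gate and must be killed by the symmetry gate).
    """

    positive_fraction: float = Field(0.0, ge=0.0, le=1.0)
    accumulation_rate: float = 8.0
    cross_talk_fraction: float = Field(0.0, ge=0.0, le=1.0)
    arc_fraction: float = Field(0.25, gt=0.0, le=1.0)


class NoiseModel(BaseModel):
    sigma: float = Field(2.0, ge=0.0)
    background_bf: float = 200.0
    background_fluor: float = 20.0


class SceneConfig(BaseModel):
    """Full description of a synthetic plate scene."""

    lattice: Literal["square", "hex"] = "square"
    pitch_um: float = 130.0
    bottom_diam_um: float = 65.0
    pixel_size_um: float = 2.0  # desk scale; instrument-native is 0.5
    grid_rows: int = Field(10, ge=1)
    grid_cols: int = Field(10, ge=1)
    n_timepoints: int = Field(7, ge=1)
    interval_hours: float = Field(4.0, gt=0.0)
    channels: tuple[str, ...] = ("BF",)
    loading_density: float = Field(1.0, ge=0.0)  # lambda, cells per microwell
    fixed_occupancy: Optional[int] = None  # e.g. 2 for defined co-cultures
    growth_model: GrowthModel = GrowthModel()
    secretion_model: SecretionModel = SecretionModel()
    marker_fractions: dict[str, float] = {}
    cell_diam_um: float = 10.0
    ring_depth: float = 80.0  # BF contrast of the microwell wall ring
    cell_contrast_bf: float = 60.0
    cell_brightness_fluor: float = 200.0
    drift_px_per_t: tuple[int, int] = (0, 0)
    noise: NoiseModel = NoiseModel()
    max_frame_bytes: int = 2 * 1024**3
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SceneConfig":
        if self.pitch_um <= self.bottom_diam_um:
            raise ValueError("pitch_um must exceed bottom_diam_um")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name, frac in self.marker_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"marker fraction for {name!r} outside [0,1]")
        return self

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.pixel_size_um

    @property
    def bottom_radius_px(self) -> float:
        return 0.5 * self.bottom_diam_um / self.pixel_size_um

    @property
    def n_microwells(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def times_hours(self) -> np.ndarray:
        return np.arange(self.n_timepoints, dtype=float) * self.interval_hours


def preset(name: str, **overrides) -> SceneConfig:
    """Named study conditions.

    ``nalm6_default``
        Suspension cancer line loaded at one cell per microwell on
        average, imaged every 4 h for 4 days; clonal division rates
        lognormal with median 0.8 divisions/day.
    ``peptide_pulsed``
        1:1 co-cultures with a cytokine channel; 40% of co-cultures are
        secretion-positive and 5% are cross-talk victims.
    """
    presets = {
        "nalm6_default": dict(
            channels=("BF",),
            loading_density=1.0,
            n_timepoints=25,
            interval_hours=4.0,
            growth_model=GrowthModel(
                median_rate_div_per_day=0.8, sigma=0.4, death_fraction=0.05
            ),
        ),
        "peptide_pulsed": dict(
            channels=("BF", "IFNg"),
            fixed_occupancy=2,
            n_timepoints=7,
            interval_hours=4.0,
            growth_model=GrowthModel(median_rate_div_per_day=0.0, sigma=0.0,
                                     death_fraction=0.0),
            secretion_model=SecretionModel(
                positive_fraction=0.40,
                cross_talk_fraction=0.05,
                accumulation_rate=8.0,
            ),
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; have {sorted(presets)}")
    kw = dict(presets[name])
    kw.update(overrides)
    return SceneConfig(**kw)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SceneTruth:
    """Per-microwell ground truth backing every downstream test.

    ``table`` has one row per lattice site (id, lattice index, center,
    occupancy at t0, true division rate, secretion label, marker class);
    ``trajectories`` is the (n_microwells, n_timepoints) integer count
    matrix; ``drift`` the applied global (dy, dx) per timepoint.
    """

    table: pd.DataFrame
    trajectories: np.ndarray
    drift: np.ndarray
    times_hours: np.ndarray
    config: SceneConfig = field(repr=False)

    def __post_init__(self) -> None:
        n, t = self.trajectories.shape
        assert len(self.table) == n, "one record per lattice site"
        assert t == len(self.times_hours)
        assert (self.trajectories >= 0).all(), "counts are non-negative"

    @property
    def n_microwells(self) -> int:
        return len(self.table)

    def long_table(self) -> pd.DataFrame:
        """One row per microwell-timepoint (count + static truth columns)."""
        n, t = self.trajectories.shape
        rows = self.table.loc[self.table.index.repeat(t)].reset_index(drop=True)
        rows["timepoint"] = np.tile(np.arange(t), n)
        rows["time_hours"] = np.tile(self.times_hours, n)
        rows["count"] = self.trajectories.ravel()
        return rows

    def write(self, csv_path, json_path=None) -> None:
        self.long_table().to_csv(csv_path, index=False)
        if json_path is not None:
            meta = {
                "config": json.loads(self.config.model_dump_json()),
                "drift": self.drift.tolist(),
                "times_hours": self.times_hours.tolist(),
            }
            Path(json_path).write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# loading and growth


def simulate_loading(n_cells: int, n_microwells: int, seed) -> np.ndarray:
    """Distribute ``n_cells`` over ``n_microwells`` equiprobable sites.

    Multinomial with equal site probabilities — the stochastic seeding
    whose per-site occupancy converges to Poisson(lambda) with
    lambda = n_cells / n_microwells.  The draw conserves the total
    exactly.
    """
    if not float(n_cells).is_integer() or not float(n_microwells).is_integer():
        raise ValueError("n_cells and n_microwells must be integers")
    n_cells, n_microwells = int(n_cells), int(n_microwells)
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    if n_microwells < 1:
        raise ValueError("n_microwells must be at least 1")
    rng = np.random.default_rng(seed)
    occ = rng.multinomial(n_cells, np.full(n_microwells, 1.0 / n_microwells))
    return occ.astype(np.int64)


def draw_division_rates(n: int, model: GrowthModel, rng: np.random.Generator) -> np.ndarray:
    """Per-microwell division rates (div/day), negative for the death fraction."""
    r = model.median_rate_div_per_day * np.exp(
        model.sigma * rng.standard_normal(n)
    )
    if model.median_rate_div_per_day == 0.0:
        r = np.zeros(n)
    dying = rng.random(n) < model.death_fraction
    # decay rates: lognormal around 0.5 halvings/day
    r[dying] = -0.5 * np.exp(0.5 * rng.standard_normal(int(dying.sum())))
    return r


def simulate_growth(
    occupancy: np.ndarray,
    growth_model: GrowthModel,
    times_hours: np.ndarray,
    seed,
    rates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic-exponential trajectories with one random rate per site.

    ``n_i(t) = round_half_up(n_i(0) * 2**(r_i * t_days))``; a trajectory
    that reaches 0 stays 0, and empty microwells stay empty.  Returns
    ``(trajectories, rates)`` with trajectories shaped
    (n_microwells, n_timepoints).
    """
    times_hours = np.asarray(times_hours, dtype=float)
    if times_hours.ndim != 1 or (len(times_hours) > 1 and not np.all(np.diff(times_hours) > 0)):
        raise ValueError("times_hours must be strictly increasing")
    occupancy = np.asarray(occupancy, dtype=np.int64)
    rng = np.random.default_rng(seed)
    if rates is None:
        rates = draw_division_rates(len(occupancy), growth_model, rng)
    t_days = times_hours / 24.0
    raw = occupancy[:, None] * np.power(2.0, np.outer(rates, t_days))
    counts = np.floor(raw + 0.5).astype(np.int64)  # round half-up
    counts[occupancy == 0] = 0
    # absorbing zero: once extinct, stay extinct
    extinct = np.minimum.accumulate(counts, axis=1) == 0
    counts[extinct] = 0
    return counts, rates


def add_count_noise(
    trajectories: np.ndarray, p: float = 0.1, seed=0
) -> np.ndarray:
    """Miscount noise: each nonzero count gains +/-1 with probability ``p``.

    Emulates segmentation errors (merged or spurious blobs).  Zero
    counts are left untouched — an empty microwell is rarely miscounted.
    """
    rng = np.random.default_rng(seed)
    traj = np.asarray(trajectories).copy()
    flip = rng.random(traj.shape) < p
    delta = rng.choice([-1, 1], size=traj.shape)
    noisy = np.where(flip & (traj > 0), traj + delta, traj)
    return np.maximum(noisy, 0)


# ---------------------------------------------------------------------------
# rendering


def _lattice_centers(config: SceneConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(y, x) centers at t0, row and col index arrays, row-major order."""
    pitch = config.pitch_px
    margin = math.ceil(pitch)
    rows = np.repeat(np.arange(config.grid_rows), config.grid_cols)
    cols = np.tile(np.arange(config.grid_cols), config.grid_rows)
    y = margin + rows * pitch
    x = margin + cols * pitch
    if config.lattice == "hex":
        y = margin + rows * pitch * math.sqrt(3) / 2
        x = x + (rows % 2) * pitch / 2
    return np.column_stack([y, x]), rows, cols


def _frame_shape(config: SceneConfig, centers: np.ndarray) -> tuple[int, int]:
    margin = math.ceil(config.pitch_px)
    max_drift_y = abs(config.drift_px_per_t[0]) * (config.n_timepoints - 1)
    max_drift_x = abs(config.drift_px_per_t[1]) * (config.n_timepoints - 1)
    h = int(math.ceil(centers[:, 0].max())) + margin + max_drift_y + 1
    w = int(math.ceil(centers[:, 1].max())) + margin + max_drift_x + 1
    return h, w


def _cell_slots(config: SceneConfig, rng: np.random.Generator, n_slots: int = 64) -> np.ndarray:
    """Packed (dy, dx) offsets inside the well bottom, closest-first."""
    spacing = config.cell_diam_um / config.pixel_size_um + 1.0
    wall_w = max(2.0, 4.0 / config.pixel_size_um)
    # keep whole cell footprints clear of the wall ring
    reach = (
        config.bottom_radius_px
        - 0.5 * config.cell_diam_um / config.pixel_size_um
        - wall_w / 2
        - 1.5
    )
    pts = []
    k = int(math.ceil(reach / spacing)) + 1
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            dy = i * spacing * math.sqrt(3) / 2
            dx = (j + 0.5 * (i % 2)) * spacing
            if math.hypot(dy, dx) <= max(reach, 0.5):
                pts.append((dy, dx))
    pts.sort(key=lambda p: math.hypot(*p))
    return np.asarray(pts[:n_slots]) if pts else np.zeros((1, 2))


def _assign_secretion_labels(
    config: SceneConfig, occupied: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exact-count label planting among occupied microwells.

    round(positive_fraction * n_occupied) sites become 'positive' and
    round(cross_talk_fraction * n_occupied) of the remainder become
    'cross_talk_victim', assigned by a seeded permutation; empty sites
    are labelled 'empty'.
    """
    n = len(occupied)
    labels = np.full(n, "negative", dtype=object)
    labels[~occupied] = "empty"
    occ_idx = np.flatnonzero(occupied)
    n_occ = len(occ_idx)
    n_pos = int(round(config.secretion_model.positive_fraction * n_occ))
    n_ct = int(round(config.secretion_model.cross_talk_fraction * n_occ))
    perm = rng.permutation(occ_idx)
    labels[perm[:n_pos]] = "positive"
    labels[perm[n_pos:n_pos + n_ct]] = "cross_talk_victim"
    return labels


def render_scene(config: SceneConfig) -> tuple[FrameStack, MicrowellGrid, SceneTruth]:
    """Render a full TCZYX scene plus ground-truth grid and truth record.

    Rendering order per timepoint: background, microwell rings (BF),
    cells, secretion rings/arcs, whole-frame integer drift (applied by
    shifting all draw positions), then Gaussian noise.  The returned
    :class:`MicrowellGrid` is the *true* grid (centers, ids, shifts), so
    detection can be scored against it.
    """
    rng = np.random.default_rng(config.seed)
    centers, rows, cols = _lattice_centers(config)
    n = len(centers)
    h, w = _frame_shape(config, centers)
    nbytes = (
        config.n_timepoints * len(config.channels) * h * w * np.dtype(np.float32).itemsize
    )
    if nbytes > config.max_frame_bytes:
        raise ValueError(
            f"scene would need a {config.n_timepoints}x{len(config.channels)}"
            f"x1x{h}x{w} float32 stack ({nbytes / 1e9:.2f} GB) exceeding "
            f"max_frame_bytes={config.max_frame_bytes}; reduce the grid or "
            f"coarsen pixel_size_um"
        )

    # --- occupancy, growth, labels ------------------------------------
    if config.fixed_occupancy is not None:
        occupancy = np.full(n, config.fixed_occupancy, dtype=np.int64)
    else:
        n_cells = int(round(config.loading_density * n))
        occupancy = simulate_loading(n_cells, n, rng.integers(2**31))
    trajectories, rates = simulate_growth(
        occupancy, config.growth_model, config.times_hours, rng.integers(2**31)
    )
    labels = _assign_secretion_labels(config, occupancy > 0, rng)

    # marker class per microwell (all cells in a clone share the marker)
    marker = np.full(n, "", dtype=object)
    fluor_channels = [c for c in config.channels if c != "BF"]
    marker_channels = [c for c in fluor_channels if c in config.marker_fractions]
    if marker_channels:
        occ_idx = np.flatnonzero(occupancy > 0)
        perm = rng.permutation(occ_idx)
        start = 0
        for ch in marker_channels:
            k = int(round(config.marker_fractions[ch] * len(occ_idx)))
            marker[perm[start:start + k]] = ch
            start += k

    # --- stencil precomputation ---------------------------------------
    pitch = config.pitch_px
    r_bottom = config.bottom_radius_px
    cell_r = 0.5 * config.cell_diam_um / config.pixel_size_um
    patch_r = int(math.ceil(pitch / 2))  # half-side of the draw patch
    side = 2 * patch_r + 1
    yy, xx = np.mgrid[-patch_r:patch_r + 1, -patch_r:patch_r + 1]
    dist = np.hypot(yy, xx)
    ang = np.arctan2(yy, xx)  # [-pi, pi]

    wall_w = max(2.0, 4.0 / config.pixel_size_um)
    ring_mask = np.abs(dist - r_bottom) <= wall_w / 2  # BF dark ring

    ann_in = 0.25 * pitch + 1.0
    ann_out = 0.475 * pitch - 1.0
    annulus = (dist >= ann_in) & (dist <= ann_out)
    ann_area = int(annulus.sum())

    arc_phase = rng.uniform(0, 2 * math.pi, size=n)  # victim arc orientation
    slots = _cell_slots(config, rng)
    slot_jitter = rng.uniform(-0.5, 0.5, size=(n, 2))  # per-microwell, static

    drift = np.array(
        [
            (t * config.drift_px_per_t[0], t * config.drift_px_per_t[1])
            for t in range(config.n_timepoints)
        ],
        dtype=np.int64,
    )

    def stamp(frame, cy, cx, mask, value):
        iy, ix = int(round(cy)), int(round(cx))
        frame[iy - patch_r:iy + patch_r + 1, ix - patch_r:ix + patch_r + 1][mask] += value

    def stamp_disk(frame, cy, cx, radius, value):
        iy, ix = int(round(cy)), int(round(cx))
        r = int(math.ceil(radius))
        gy, gx = np.mgrid[-r:r + 1, -r:r + 1]
        disk = np.hypot(gy + (cy - iy), gx + (cx - ix)) <= radius
        frame[iy - r:iy + r + 1, ix - r:ix + r + 1][disk] += value

    # --- render -------------------------------------------------------
    stack = np.zeros(
        (config.n_timepoints, len(config.channels), 1, h, w), dtype=np.float32
    )
    sm = config.secretion_model
    arc_half = sm.arc_fraction * math.pi  # half-angle of the victim arc
    for t in range(config.n_timepoints):
        dy, dx = drift[t]
        t_hours = config.times_hours[t]
        for ci, ch in enumerate(config.channels):
            frame = stack[t, ci, 0]
            frame[:] = (
                config.noise.background_bf if ch == "BF" else config.noise.background_fluor
            )
            for i in range(n):
                cy, cx = centers[i, 0] + dy, centers[i, 1] + dx
                count = int(trajectories[i, t])
                if ch == "BF":
                    stamp(frame, cy, cx, ring_mask, -config.ring_depth)
                    for s in range(min(count, len(slots))):
                        stamp_disk(
                            frame,
                            cy + slots[s, 0] + slot_jitter[i, 0],
                            cx + slots[s, 1] + slot_jitter[i, 1],
                            cell_r,
                            -config.cell_contrast_bf,
                        )
                elif ch in marker_channels:
                    if marker[i] == ch:
                        for s in range(min(count, len(slots))):
                            stamp_disk(
                                frame,
                                cy + slots[s, 0] + slot_jitter[i, 0],
                                cx + slots[s, 1] + slot_jitter[i, 1],
                                cell_r,
                                config.cell_brightness_fluor,
                            )
                else:  # cytokine channel
                    amp = sm.accumulation_rate * t_hours
                    if amp <= 0:
                        continue
                    if labels[i] == "positive":
                        stamp(frame, cy, cx, annulus, amp)
                    elif labels[i] == "cross_talk_victim":
                        dphi = np.angle(np.exp(1j * (ang - arc_phase[i])))
                        arc = annulus & (np.abs(dphi) <= arc_half)
                        n_arc = int(arc.sum())
                        if n_arc:
                            # same total as a full ring of this amplitude
                            stamp(frame, cy, cx, arc, amp * ann_area / n_arc)
        if config.noise.sigma > 0:
            stack[t] += rng.normal(
                0.0, config.noise.sigma, size=stack[t].shape
            ).astype(np.float32)

    fstack = FrameStack(
        data=stack,
        channel_names=list(config.channels),
        timestamps_hours=config.times_hours,
        pixel_size_um=config.pixel_size_um,
        meta={"generator": "conewell.scene_sim", "seed": config.seed},
    )

    grid = MicrowellGrid(
        ids=np.arange(n, dtype=np.int64),
        centers_t0=centers.astype(float),
        lattice_rows=rows,
        lattice_cols=cols,
        shifts=drift.astype(float),
        pitch_px=pitch,
        pixel_size_um=config.pixel_size_um,
        accessible=np.ones(n, dtype=bool),
        detection_score=np.ones(n),
    )

    table = pd.DataFrame(
        {
            "microwell_id": np.arange(n, dtype=np.int64),
            "row": rows,
            "col": cols,
            "center_y": centers[:, 0],
            "center_x": centers[:, 1],
            "occupancy_t0": occupancy,
            "r_true": rates,
            "secretion_label": labels,
            "marker": marker,
        }
    )
    truth = SceneTruth(
        table=table,
        trajectories=trajectories,
        drift=drift,
        times_hours=config.times_hours,
        config=config,
    )
    return fstack, grid, truth
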