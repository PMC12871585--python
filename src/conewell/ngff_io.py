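"""Image and table I/O.

Image stacks live in OME-NGFF-style zarr groups with a fixed TCZYX axis
order (time, channel, focal plane, y, x).  Feature tables are long-format
CSV keyed by (well, microwell_id, timepoint).  All round-trips are
lossless for the declared columns; coordinates are stored 0-based (y, x)
in pixels with micron conversion happening only at module boundaries via
``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
import zarr

AXES = "tczyx"

#: Columns that uniquely key a feature-table row.
FEATURE_KEY = ["well", "microwell_id", "timepoint"]


class FormatError(ValueError):
    """Raised when a store does not satisfy the TCZYX contract."""


@dataclass
class FrameStack:
    """A TCZYX image stack with channel names and acquisition times.

    ``data`` may be an in-memory ndarray or a lazily-loaded zarr array;
    both expose the same slicing interface.  ``timestamps_hours`` are
    hours since the first frame and must be strictly increasing.
    """

    data: object  # ndarray or zarr.Array, shape (T, C, Z, Y, X)
    channel_names: Sequence[str]
    timestamps_hours: np.ndarray
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if getattr(self.data, "ndim", None) != 5:
            raise FormatError(
                f"FrameStack data must be 5-D TCZYX, got ndim={getattr(self.data, 'ndim', None)}"
            )
        t, c = self.data.shape[:2]
        self.timestamps_hours = np.asarray(self.timestamps_hours, dtype=float)
        if len(self.channel_names) != c:
            raise FormatError(
                f"{len(self.channel_names)} channel names for C={c} channels"
            )
        if len(self.timestamps_hours) != t:
            raise FormatError(
                f"{len(self.timestamps_hours)} timestamps for T={t} timepoints"
            )
        if t > 1 and not np.all(np.diff(self.timestamps_hours) > 0):
            raise FormatError("timestamps must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple:
        return tuple(self.data.shape)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in stack (have {list(self.channel_names)})"
            ) from None

    def frame(self, t: int, channel: str | int) -> np.ndarray:
        """Single 2-D plane at timepoint ``t`` (max-projected over Z)."""
        c = channel if isinstance(channel, int) else self.channel_index(channel)
        plane = np.asarray(self.data[t, c])
        return plane.max(axis=0) if plane.shape[0] > 1 else plane[0]

    def asarray(self) -> np.ndarray:
        return np.asarray(self.data)


def write_stack(stack: FrameStack, path) -> None:
    """Write ``stack`` to an OME-NGFF zarr group at ``path``.

    The group carries NGFF 0.4 ``multiscales`` metadata (single scale
    level at array path "0") plus ``omero`` channel names; acquisition
    timestamps and pixel size go in the same attribute block so a
    round-trip through :func:`open_stack` is metadata-lossless.
    """
    path = Path(path)
    data = np.asarray(stack.data)
    grp = zarr.open_group(str(path), mode="w", zarr_format=2)
    arr = grp.create_array(
        "0",
        shape=data.shape,
        dtype=data.dtype,
        chunks=(1, 1, data.shape[2], data.shape[3], data.shape[4]),
    )
    arr[:] = data
    scale_t = float(np.diff(stack.timestamps_hours).mean()) if len(stack.timestamps_hours) > 1 else 1.0
    grp.attrs["multiscales"] = [
        {
            "version": "0.4",
            "name": path.stem,
            "axes": [
                {"name": "t", "type": "time", "unit": "hour"},
                {"name": "c", "type": "channel"},
                {"name": "z", "type": "space", "unit": "micrometer"},
                {"name": "y", "type": "space", "unit": "micrometer"},
                {"name": "x", "type": "space", "unit": "micrometer"},
            ],
            "datasets": [
                {
                    "path": "0",
                    "coordinateTransformations": [
                        {
                            "type": "scale",
                            "scale": [scale_t, 1.0, 1.0, stack.pixel_size_um, stack.pixel_size_um],
                        }
                    ],
                }
            ],
        }
    ]
    grp.attrs["omero"] = {
        "channels": [{"label": str(n)} for n in stack.channel_names]
    }
    grp.attrs["conewell"] = {
        "timestamps_hours": [float(t) for t in stack.timestamps_hours],
        "pixel_size_um": float(stack.pixel_size_um),
        "meta": _jsonable(stack.meta),
    }


def open_stack(path, interval_hours: float | None = None) -> FrameStack:
    """Open an OME-NGFF zarr group as a lazy :class:`FrameStack`.

    Only attributes are touched here; pixel chunks load on slicing.
    Missing timestamps fall back to ``index * interval_hours`` with a
    warning.  A store whose axes are not exactly TCZYX is rejected
    (never silently transposed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        grp = zarr.open_group(str(path), mode="r")
        multiscales = grp.attrs["multiscales"]
    except (KeyError, Exception) as exc:  # noqa: B014 - zarr raises several types
        if isinstance(exc, KeyError):
            raise FormatError(f"{path}: no multiscales metadata (not an OME-NGFF group)")
        raise FormatError(f"{path}: not a readable zarr group ({exc})")
    axes = "".join(a["name"].lower() for a in multiscales[0]["axes"])
    if axes != AXES:
        raise FormatError(
            f"{path}: axis order {axes.upper()!r} but the contract requires 'TCZYX'"
        )
    arr = grp[multiscales[0]["datasets"][0]["path"]]
    t, c = arr.shape[:2]

    omero = grp.attrs.get("omero", {})
    channel_names = [ch.get("label", f"C{i}") for i, ch in enumerate(omero.get("channels", []))]
    if len(channel_names) != c:
        channel_names = [f"C{i}" for i in range(c)]

    side = grp.attrs.get("conewell", {})
    if "timestamps_hours" in side:
        timestamps = np.asarray(side["timestamps_hours"], dtype=float)
    else:
        step = interval_hours if interval_hours is not None else 1.0
        warnings.warn(
            f"{path}: no timestamps stored; defaulting to index * {step} h",
            stacklevel=2,
        )
        timestamps = np.arange(t, dtype=float) * step

    pixel_size = float(side.get("pixel_size_um", 0) or 0)
    if pixel_size <= 0:
        # fall back to the NGFF scale transform on the x axis
        tforms = multiscales[0]["datasets"][0].get("coordinateTransformations", [])
        scales = [tf["scale"] for tf in tforms if tf.get("type") == "scale"]
        pixel_size = float(scales[0][-1]) if scales else 1.0

    return FrameStack(
        data=arr,
        channel_names=channel_names,
        timestamps_hours=timestamps,
        pixel_size_um=pixel_size,
        meta=dict(side.get("meta", {})),
    )


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a long-format feature table as CSV (lossless round-trip)."""
    missing = [k for k in FEATURE_KEY if k not in table.columns]
    if missing:
        raise ValueError(f"feature table missing key columns {missing}")
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV, rejecting duplicate (well, id, t) keys."""
    df = pd.read_csv(path)
    missing = [k for k in FEATURE_KEY if k not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing key columns {missing}")
    if len(df) and df.duplicated(subset=FEATURE_KEY).any():
        dupes = df[df.duplicated(subset=FEATURE_KEY, keep=False)][FEATURE_KEY]
        raise ValueError(f"{path}: duplicate feature keys:\n{dupes.head()}")
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
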