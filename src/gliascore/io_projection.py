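"""Reading image stacks and collapsing them to maximum-intensity projections.

A :class:`ChannelStack` holds one 3-D array of Z-planes per named channel
(nucleus/DAPI, microglia/Iba1, astrocyte/GFAP, neurofilament). Stacks are
merged to a 2-D :class:`Projection` by the per-pixel maximum over planes,
which is the standard way to collapse a thin fluorescence volume while
keeping every structure at its brightest focal plane.

Rasters are row-major with the origin at the top-left. Intensities are
stored as 16-bit unsigned; 8-bit input is up-scaled by 257 so that the full
dynamic range maps onto the 16-bit one. Channels are kept as separate named
planes, never fused into an RGB composite: the display colors of the stains
are presentation, not data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

CHANNEL_LABELS = ("nucleus", "microglia", "astrocyte", "neurofilament")

DEFAULT_MAX_PLANES = 30
DEFAULT_PLANE_SPACING_UM = 0.24


def _as_uint16(plane: np.ndarray) -> np.ndarray:
    """Coerce a raster to uint16, up-scaling 8-bit input."""
    arr = np.asarray(plane)
    if arr.ndim != 2:
        raise ValueError(f"plane must be 2-D, got shape {arr.shape}")
    if arr.dtype == np.uint16:
        return arr
    if arr.dtype == np.uint8:
        return arr.astype(np.uint16) * 257
    if np.issubdtype(arr.dtype, np.integer) or np.issubdtype(arr.dtype, np.floating):
        if np.any(arr < 0) or np.any(arr > 65535):
            raise ValueError("intensities must lie in [0, 65535]")
        return arr.astype(np.uint16)
    raise ValueError(f"unsupported raster dtype {arr.dtype}")


@dataclass
class ChannelStack:
    """Registered multi-channel Z-stack.

    Parameters
    ----------
    channels:
        Mapping channel label -> (n_planes, rows, cols) uint16 array. All
        channels share one raster shape and plane count. Absent channels are
        simply missing keys (single- and double-stain inputs are common).
    plane_spacing_um:
        Axial spacing between consecutive planes, micrometres.
    pixel_size_um:
        Lateral pixel size (metadata only; no measurement here uses it).
    max_planes:
        Configurable cap on the number of planes per stack.
    """

    channels: dict[str, np.ndarray]
    plane_spacing_um: float = DEFAULT_PLANE_SPACING_UM
    pixel_size_um: float | None = None
    max_planes: int = DEFAULT_MAX_PLANES

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("stack must contain at least one channel")
        if self.plane_spacing_um <= 0:
            raise ValueError("plane_spacing_um must be positive")
        coerced: dict[str, np.ndarray] = {}
        shape = None
        for label, planes in self.channels.items():
            if label not in CHANNEL_LABELS:
                raise ValueError(
                    f"unknown channel label {label!r}; expected one of {CHANNEL_LABELS}"
                )
            arr = np.asarray(planes)
            if arr.ndim == 2:
                arr = arr[None]
            if arr.ndim != 3:
                raise ValueError(f"channel {label!r} must be (planes, rows, cols)")
            arr = np.stack([_as_uint16(p) for p in arr])
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"channel {label!r} shape {arr.shape} differs from {shape}"
                )
            coerced[label] = arr
        n_planes = shape[0]
        if n_planes < 1:
            raise ValueError("stack must contain at least one plane")
        if n_planes > self.max_planes:
            raise ValueError(
                f"stack has {n_planes} planes, exceeding max_planes={self.max_planes}"
            )
        self.channels = coerced

    @property
    def n_planes(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return tuple(self.channels)


@dataclass
class Projection:
    """Per-channel 2-D maximum-intensity rasters of one stack."""

    channels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("projection must contain at least one channel")
        shape = None
        for label, raster in self.channels.items():
            arr = _as_uint16(raster)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError("projection channels must share one shape")
            self.channels[label] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def image_area_px(self) -> int:
        rows, cols = self.shape
        return rows * cols

    def channel(self, label: str) -> np.ndarray:
        if label not in self.channels:
            raise KeyError(f"channel {label!r} absent from projection")
        return self.channels[label]


def read_stack(
    path: str | Path,
    channel_map: Mapping[str, int] | None = None,
    *,
    plane_spacing_um: float = DEFAULT_PLANE_SPACING_UM,
    max_planes: int = DEFAULT_MAX_PLANES,
) -> ChannelStack:
    """Read a TIFF / OME-TIFF into a validated :class:`ChannelStack`.

    Parameters
    ----------
    path:
        TIFF file. Accepted layouts: (rows, cols) single plane/channel,
        (planes, rows, cols) single channel, or (planes, channels, rows,
        cols) / (channels, planes, rows, cols) multi-channel (the channel
        axis is taken to be the smaller of the two leading axes).
    channel_map:
        label -> channel index. Required for multi-channel files; for
        single-channel files it defaults to ``{"nucleus": 0}`` unless a
        single-entry map names the channel. Missing labels are permitted
        and simply absent from the result.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, None]  # -> (planes=1, channels=1, r, c)
    elif data.ndim == 3:
        data = data[:, None]  # single channel
    elif data.ndim == 4:
        # axis with fewer entries is the channel axis
        if data.shape[1] > data.shape[0]:
            data = np.moveaxis(data, 0, 1)  # (C, Z, r, c) -> (Z, C, r, c)
    else:
        raise ValueError(f"unsupported TIFF layout with shape {data.shape}")

    n_channels = data.shape[1]
    if channel_map is None:
        if n_channels != 1:
            raise ValueError("channel_map is required for multi-channel files")
        channel_map = {"nucleus": 0}
    for label in channel_map:
        if label not in CHANNEL_LABELS:
            raise ValueError(f"unknown channel label {label!r}")
    for label, idx in channel_map.items():
        if not 0 <= idx < n_channels:
            raise ValueError(
                f"channel {label!r} maps to index {idx}, file has {n_channels}"
            )
    channels = {label: data[:, idx] for label, idx in channel_map.items()}
    return ChannelStack(
        channels=channels,
        plane_spacing_um=plane_spacing_um,
        max_planes=max_planes,
    )


def max_intensity_projection(stack: ChannelStack) -> Projection:
    """Collapse a Z-stack to its per-pixel maximum over planes, per channel."""
    if not stack.channels:
        raise ValueError("empty stack")
    return Projection(
        channels={label: planes.max(axis=0) for label, planes in stack.channels.items()}
    )


def write_projection(projection: Projection, directory: str | Path, stem: str = "projection") -> list[Path]:
    """Write each channel of a projection as a single-page TIFF.

    Returns the written paths (``<stem>_<label>.tif``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, raster in projection.channels.items():
        out = directory / f"{stem}_{label}.tif"
        tifffile.imwrite(out, raster)
        paths.append(out)
    return paths
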