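"""Zone-of-influence ring construction and process counting.

Each detected nucleus (primary object) is surrounded by an annular ring: a
gap of 9 one-pixel distance shells is left between the nucleus boundary and
the ring, and the ring itself spans 14 shells. Microglial processes are the
connected runs of microglia-channel object pixels inside the ring
(8-connectivity within the ring subgraph): runs separated by background
count as separate processes. This is a fixed-radius cousin of Sholl
analysis with a single annulus per cell.

Distance shells are ``floor(d)`` of the Euclidean distance transform from
the nucleus pixel set, so shell *k* collects the k-th one-pixel layer
around the nucleus; a chessboard (8-neighborhood chamfer) variant is
selectable for users who want square rings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from gliascore.config import DEFAULT_CONFIG, PipelineConfig
from gliascore.io_projection import Projection
from gliascore.nuclei import NucleusRecord
from gliascore.segmentation import SegmentationMask

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class InfluenceZone:
    """Annular ring around one nucleus in which processes are counted."""

    nucleus_id: int
    ring: np.ndarray  # boolean raster, True on ring pixels
    gap_px: int
    width_px: int
    border_clipped: bool

    def __post_init__(self) -> None:
        if self.ring.dtype != bool:
            raise ValueError("ring must be boolean")
        if not self.ring.any():
            raise ValueError("ring is empty (entirely outside the image)")


@dataclass
class MicrogliaRecord:
    """Per-cell scored entity: nucleus metrics plus ring morphometry."""

    nucleus: NucleusRecord
    process_count: int
    border_clipped: bool = False
    overlap_flag: bool = False
    activity_class: str | None = None  # assigned by the activity module only

    def __post_init__(self) -> None:
        if self.process_count < 0:
            raise ValueError("process_count must be non-negative")


def _nucleus_raster(nucleus: NucleusRecord, shape: tuple[int, int]) -> np.ndarray:
    raster = np.zeros(shape, dtype=bool)
    rows, cols = nucleus.pixels[:, 0], nucleus.pixels[:, 1]
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
        raise ValueError("nucleus pixels outside image")
    raster[rows, cols] = True
    return raster


def _distance_shells(
    nucleus_raster: np.ndarray, metric: Literal["euclidean", "chessboard"]
) -> np.ndarray:
    """Integer shell index per pixel: floor of distance to the nucleus set."""
    if metric == "euclidean":
        d = ndimage.distance_transform_edt(~nucleus_raster)
        return np.floor(d).astype(np.int64)
    if metric == "chessboard":
        return ndimage.distance_transform_cdt(
            ~nucleus_raster, metric="chessboard"
        ).astype(np.int64)
    raise ValueError(f"unknown ring metric {metric!r}")


def build_influence_zone(
    nucleus: NucleusRecord,
    shape: tuple[int, int],
    gap_px: int = DEFAULT_CONFIG.ring_gap_px,
    width_px: int = DEFAULT_CONFIG.ring_width_px,
    metric: Literal["euclidean", "chessboard"] = "euclidean",
) -> InfluenceZone:
    """Build the ring of pixels in shells ``gap_px+1 .. gap_px+width_px``.

    The ring is clipped at image borders; a clipped ring is permitted and
    flagged via ``border_clipped``.
    """
    if gap_px < 0:
        raise ValueError("gap_px must be non-negative")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    if nucleus.pixels.size == 0:
        raise ValueError("nucleus has no pixels")

    # pad so the ideal (unclipped) ring can be compared with the clipped one
    pad = gap_px + width_px + 1
    padded_shape = (shape[0] + 2 * pad, shape[1] + 2 * pad)
    padded = np.zeros(padded_shape, dtype=bool)
    padded[nucleus.pixels[:, 0] + pad, nucleus.pixels[:, 1] + pad] = True
    shells = _distance_shells(padded, metric)
    ring_padded = (shells > gap_px) & (shells <= gap_px + width_px)
    ring = ring_padded[pad : pad + shape[0], pad : pad + shape[1]]
    clipped = bool(ring_padded.sum() != ring.sum())
    return InfluenceZone(
        nucleus_id=nucleus.id,
        ring=ring,
        gap_px=gap_px,
        width_px=width_px,
        border_clipped=clipped,
    )


def count_processes(zone: InfluenceZone, microglia_mask: SegmentationMask) -> int:
    """Count connected microglia-signal runs inside the ring.

    Components are 8-connected within the ring subgraph: signal separated by
    background pixels, or leaving and re-entering the ring, forms separate
    processes.
    """
    if microglia_mask.shape != zone.ring.shape:
        raise ValueError("mask and ring shapes differ")
    inside = microglia_mask.mask & zone.ring
    _, n = ndimage.label(inside, structure=_STRUCT8)
    return int(n)


def score_microglia(
    projection: Projection,
    nuclei: list[NucleusRecord],
    microglia_mask: SegmentationMask,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[MicrogliaRecord]:
    """Score every accepted nucleus: ring construction plus process count.

    The nucleus's own pixels are removed from the counting mask so that a
    lobulated soma reaching into its own ring is not counted as a process.
    Rings overlapping another cell's ring or nucleus are flagged
    (``overlap_flag``) so users can filter ambiguous counts; components
    belonging to a neighboring cell are still counted.
    """
    if microglia_mask.shape != projection.shape:
        raise ValueError("mask and projection shapes differ")
    zones = [
        build_influence_zone(
            n,
            projection.shape,
            gap_px=config.ring_gap_px,
            width_px=config.ring_width_px,
            metric=config.ring_metric,
        )
        for n in nuclei
    ]
    # coverage count over all rings and nuclei to detect overlaps
    coverage = np.zeros(projection.shape, dtype=np.int16)
    for zone, nucleus in zip(zones, nuclei):
        coverage[zone.ring] += 1
        coverage[nucleus.pixels[:, 0], nucleus.pixels[:, 1]] += 1

    records = []
    for zone, nucleus in zip(zones, nuclei):
        own = _nucleus_raster(nucleus, projection.shape)
        counting_mask = SegmentationMask(
            mask=microglia_mask.mask & ~own,
            channel_label=microglia_mask.channel_label,
            min_object_size_px=microglia_mask.min_object_size_px,
        )
        overlap = bool((coverage[zone.ring] > 1).any())
        records.append(
            MicrogliaRecord(
                nucleus=nucleus,
                process_count=count_processes(zone, counting_mask),
                border_clipped=zone.border_clipped,
                overlap_flag=overlap,
            )
        )
    return records


def mean_process_count(records: list[MicrogliaRecord]) -> float:
    """Per-image mean process count (arithmetic mean over cells)."""
    if not records:
        raise ValueError("no microglia records")
    return float(np.mean([r.process_count for r in records]))


def records_to_frame(records: list[MicrogliaRecord], image_id: str = ""):
    """Tabulate per-cell morphometry (one CSV-ready row per cell)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "image_id": image_id,
            "nucleus_id": [r.nucleus.id for r in records],
            "process_count": [r.process_count for r in records],
            "relative_area_pct": [r.nucleus.relative_area_pct for r in records],
            "border_clipped": [r.border_clipped for r in records],
            "overlap_flag": [r.overlap_flag for r in records],
            "activity_class": [r.activity_class for r in records],
        }
    )
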