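"""End-to-end conveniences tying the pipeline stages together.

These helpers run the full measurement chain on synthetic scenes —
scribble-train the pixel classifier from the planted truth, segment,
filter, detect nuclei, measure — and are what the worked examples, tests
and the reproduction script call.
"""

from __future__ import annotations

import numpy as np

from gliascore.config import DEFAULT_CONFIG, PipelineConfig
from gliascore.nuclei import NucleusRecord, detect_nuclei
from gliascore.ring_morphometry import MicrogliaRecord, score_microglia
from gliascore.segmentation import (
    SegmentationMask,
    extract_features,
    filter_small_objects,
    segment,
    train_pixel_classifier,
)
from gliascore.synth_scenes import (
    SyntheticScene,
    generate_scene,
    random_scene_spec,
    sample_class_areas,
    scribbles_for_scene,
)


def segment_scene(
    scene: SyntheticScene,
    channels: tuple[str, ...] = ("nucleus", "microglia"),
    seed: int = 0,
    n_scribbles: int = 200,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, SegmentationMask]:
    """Scribble-train and segment the requested channels of a scene."""
    rng = np.random.default_rng(seed)
    masks = {}
    for channel in channels:
        scribbles = scribbles_for_scene(
            scene, channel, n_per_class=n_scribbles, seed=int(rng.integers(0, 2**31 - 1))
        )
        features = extract_features(scene.projection, channel)
        model = train_pixel_classifier(
            features, scribbles, scene.projection.shape, seed=int(rng.integers(0, 2**31 - 1))
        )
        masks[channel] = filter_small_objects(
            segment(scene.projection, model), min_size=config.min_object_size_px
        )
    return masks


def truth_masks(
    scene: SyntheticScene,
    channels: tuple[str, ...] = ("nucleus", "microglia"),
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, SegmentationMask]:
    """Planted object rasters wrapped as segmentation masks (oracle route)."""
    return {
        ch: SegmentationMask(
            scene.truth.object_rasters[ch], ch, config.min_object_size_px
        )
        for ch in channels
    }


def score_scene(
    scene: SyntheticScene,
    masks: dict[str, SegmentationMask] | None = None,
    seed: int = 0,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[list[NucleusRecord], list[MicrogliaRecord]]:
    """Detect nuclei and score processes on one scene."""
    if masks is None:
        masks = segment_scene(scene, seed=seed, config=config)
    records = detect_nuclei(
        scene.projection,
        masks["nucleus"],
        masks["microglia"],
        border_fraction_min=config.border_fraction_min,
        min_nucleus_size_px=config.min_object_size_px,
        split_touching=config.split_touching_nuclei,
    )
    scored = score_microglia(scene.projection, records, masks["microglia"], config)
    return records, scored


def measure_planted_class(
    label: str,
    n_cells: int,
    seed: int,
    *,
    n_replicates: int = 1,
    shape: tuple[int, int] = (512, 512),
    cells_per_scene: int = 8,
    segmentation: str = "trained",
) -> tuple[np.ndarray, np.ndarray]:
    """Plant class-conditional nucleus areas and measure them back.

    Draws ``n_replicates`` batches of ``n_cells`` relative nucleus areas
    from the class-conditional distribution, distributes each batch over as
    many scenes as needed (``cells_per_scene`` non-overlapping cells each),
    runs segmentation + nucleus detection, and returns
    ``(planted, measured)`` relative areas in percent.
    """
    rng = np.random.default_rng(seed)
    planted, measured = [], []
    for _ in range(n_replicates):
        areas = sample_class_areas(label, n_cells, rng)
        for start in range(0, len(areas), cells_per_scene):
            chunk = areas[start : start + cells_per_scene]
            spec = random_scene_spec(
                shape,
                len(chunk),
                seed=int(rng.integers(0, 2**31 - 1)),
                class_labels=[label] * len(chunk),
                target_rel_areas_pct=list(chunk),
            )
            scene = generate_scene(spec)
            if segmentation == "trained":
                masks = segment_scene(scene, seed=int(rng.integers(0, 2**31 - 1)))
            elif segmentation == "truth":
                masks = truth_masks(scene)
            else:
                raise ValueError("segmentation must be 'trained' or 'truth'")
            records = detect_nuclei(
                scene.projection, masks["nucleus"], masks["microglia"]
            )
            measured.extend(r.relative_area_pct for r in records)
            planted.extend(chunk)
    return np.asarray(planted), np.asarray(measured)
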