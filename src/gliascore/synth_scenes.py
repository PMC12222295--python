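"""Synthetic fluorescence scenes with planted ground truth.

Every pipeline stage is testable without microscope data: scenes emulate
DAPI-stained nuclei (disks), microglia with a soma rim around the nucleus
and straight radial processes (so the ring-crossing count is analytically
known), astrocyte filament networks (random walks) and parallel neurite
tracts with a tunable orientation disorder (the wild-type tracts run in
parallel; the transgenic arrangement is irregular). Ground truth — per-cell
nucleus pixels and areas, arm counts, class labels, and per-channel clean
object rasters — is recorded before noise is applied.

Default intensity model: 16-bit range, background level 3000, foreground
46000, additive Gaussian noise with SD equal to 5% of the dynamic range
(optionally Poisson), applied last.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from gliascore.activity_classes import REFERENCE_STATE_TABLE, state_sd_from_ci
from gliascore.config import DEFAULT_CONFIG, PipelineConfig
from gliascore.io_projection import ChannelStack, Projection

FOREGROUND = 46000
BACKGROUND = 3000
DYNAMIC_RANGE = 65535

#: default arm length (px) from the nucleus boundary: long enough to cross
#: the default 9+14-shell influence ring with margin
DEFAULT_ARM_LENGTH = 28
DEFAULT_ARM_WIDTH = 3
#: thickness (px) of the microglial soma rim rendered around the nucleus
SOMA_RIM = 3

#: per-class default arm counts: resting (ramified) cells carry many thin
#: processes, fully activated (amoeboid) cells almost none
CLASS_ARM_COUNTS = {
    "ramified": 5,
    "hyper_ramified": 6,
    "bushy": 3,
    "amoeboid": 1,
}


@dataclass(frozen=True)
class CellSpec:
    """One planted microglial cell."""

    center: tuple[int, int]  # (row, col)
    nucleus_radius_px: float | None = None
    target_rel_area_pct: float | None = None  # alternative to an explicit radius
    arm_count: int = 4
    arm_length_px: float = DEFAULT_ARM_LENGTH
    arm_width_px: float = DEFAULT_ARM_WIDTH
    class_label: str | None = None

    def __post_init__(self) -> None:
        if (self.nucleus_radius_px is None) == (self.target_rel_area_pct is None):
            raise ValueError("give exactly one of nucleus_radius_px / target_rel_area_pct")
        if self.nucleus_radius_px is not None and self.nucleus_radius_px < 1:
            raise ValueError("nucleus radius must be >= 1 px")
        if self.arm_count < 0:
            raise ValueError("arm_count must be >= 0")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic scene."""

    shape: tuple[int, int]
    seed: int
    cells: tuple[CellSpec, ...] = ()
    n_decoy_nuclei: int = 0  # nuclei without a microglial rim (non-microglial)
    n_astrocyte_filaments: int = 0
    n_neurite_tracts: int = 0
    neurite_disorder: float = 0.0  # SD (radians) of tract orientations
    noise_sd_frac: float = 0.05  # Gaussian SD as a fraction of dynamic range
    poisson_noise: bool = False
    background_level: int = BACKGROUND
    allow_border_cells: bool = False

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 8 or cols < 8:
            raise ValueError("scene too small")
        for cell in self.cells:
            r = _nucleus_radius(cell, rows * cols)
            reach = r + cell.arm_length_px + SOMA_RIM
            if reach > min(rows, cols):
                raise ValueError("cell arms longer than the image")
            if not self.allow_border_cells:
                cr, cc = cell.center
                if not (reach <= cr < rows - reach and reach <= cc < cols - reach):
                    raise ValueError(
                        f"cell at {cell.center} not fully inside the image "
                        "(set allow_border_cells for border cases)"
                    )


def _nucleus_radius(cell: CellSpec, image_area_px: int) -> float:
    if cell.nucleus_radius_px is not None:
        return float(cell.nucleus_radius_px)
    target_px = cell.target_rel_area_pct / 100.0 * image_area_px
    return math.sqrt(target_px / math.pi)


def _rasterize_disk(
    shape: tuple[int, int], center: tuple[int, int], target_area_px: int | None, radius: float
) -> np.ndarray:
    """Disk raster; if a target pixel count is given, the radius is tuned
    so the rasterized area matches it as closely as possible."""
    rows, cols = shape
    cr, cc = center
    yy, xx = np.ogrid[:rows, :cols]
    d2 = (yy - cr) ** 2 + (xx - cc) ** 2
    if target_area_px is None:
        return d2 <= radius * radius
    # d2 is integer: pick the integer radius-squared whose disk pixel count
    # is closest to the target
    d2_sorted = np.sort(d2.ravel())
    n = int(np.searchsorted(d2_sorted, radius * radius, side="right"))
    best_n, best_err = n, abs(n - target_area_px)
    # walk outward/inward over distinct shells near the analytic radius
    for cand in range(max(1, n - 64), min(d2_sorted.size, n + 64)):
        if cand < d2_sorted.size - 1 and d2_sorted[cand] == d2_sorted[cand - 1]:
            continue  # only complete shells keep the disk rotationally symmetric
        err = abs(cand - target_area_px)
        if err < best_err:
            best_n, best_err = cand, err
    thresh = d2_sorted[best_n - 1]
    return d2 <= thresh


def _rasterize_segment(
    shape: tuple[int, int],
    p0: tuple[float, float],
    p1: tuple[float, float],
    width: float,
) -> np.ndarray:
    """Pixels within width/2 of the segment p0-p1 (capsule rasterization)."""
    rows, cols = shape
    r0, c0 = p0
    r1, c1 = p1
    rmin = max(0, int(min(r0, r1) - width))
    rmax = min(rows, int(max(r0, r1) + width) + 1)
    cmin = max(0, int(min(c0, c1) - width))
    cmax = min(cols, int(max(c0, c1) + width) + 1)
    out = np.zeros(shape, dtype=bool)
    if rmin >= rmax or cmin >= cmax:
        return out
    yy, xx = np.mgrid[rmin:rmax, cmin:cmax]
    vr, vc = r1 - r0, c1 - c0
    vv = vr * vr + vc * vc
    if vv == 0:
        t = np.zeros_like(yy, dtype=float)
    else:
        t = np.clip(((yy - r0) * vr + (xx - c0) * vc) / vv, 0.0, 1.0)
    dr = yy - (r0 + t * vr)
    dc = xx - (c0 + t * vc)
    out[rmin:rmax, cmin:cmax] = dr * dr + dc * dc <= (width / 2.0) ** 2
    return out


def _arm_angles(rng: np.random.Generator, count: int) -> np.ndarray:
    """Evenly spaced arm angles with bounded jitter (min separation kept)."""
    if count == 0:
        return np.array([])
    base = rng.uniform(0, 2 * math.pi)
    step = 2 * math.pi / count
    jitter = rng.uniform(-0.2, 0.2, size=count) * step
    return base + step * np.arange(count) + jitter


@dataclass
class SceneTruth:
    """Planted ground truth, recorded before noise."""

    cells: pd.DataFrame  # cell_id, class_label, center, nucleus_area_px, rel_area_pct, arm_count
    object_rasters: dict[str, np.ndarray]  # channel -> clean boolean raster
    nucleus_rasters: list[np.ndarray]  # per-cell nucleus pixels
    cell_rasters: list[np.ndarray]  # per-cell microglia pixels (rim + arms)


@dataclass
class SyntheticScene:
    """Rendered channels plus planted ground truth."""

    spec: SceneSpec
    projection: Projection
    truth: SceneTruth

    @property
    def shape(self) -> tuple[int, int]:
        return self.spec.shape


def _apply_noise(clean: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    img = clean.astype(np.float64)
    if spec.poisson_noise:
        scale = 50.0
        img = rng.poisson(np.maximum(img, 0) / scale) * scale
    if spec.noise_sd_frac > 0:
        img = img + rng.normal(0.0, spec.noise_sd_frac * DYNAMIC_RANGE, size=img.shape)
    return np.clip(np.rint(img), 0, DYNAMIC_RANGE).astype(np.uint16)


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene from its spec. Identical spec + seed => identical scene."""
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    image_area = shape[0] * shape[1]

    nucleus_truth = np.zeros(shape, dtype=bool)
    microglia_truth = np.zeros(shape, dtype=bool)
    nucleus_rasters: list[np.ndarray] = []
    cell_rasters: list[np.ndarray] = []
    rows_out = []

    for cell_id, cell in enumerate(spec.cells):
        radius = _nucleus_radius(cell, image_area)
        target_px = (
            int(round(cell.target_rel_area_pct / 100.0 * image_area))
            if cell.target_rel_area_pct is not None
            else None
        )
        nucleus = _rasterize_disk(shape, cell.center, target_px, radius)
        # soma rim: a SOMA_RIM-px annulus of microglia signal hugging the
        # nucleus boundary guarantees the green-border criterion
        rim = (
            ndimage.binary_dilation(nucleus, iterations=SOMA_RIM, structure=np.ones((3, 3), bool))
            & ~nucleus
        )
        cell_raster = rim.copy()
        angles = _arm_angles(rng, cell.arm_count)
        eff_radius = math.sqrt(nucleus.sum() / math.pi)
        for theta in angles:
            dr, dc = math.sin(theta), math.cos(theta)
            start = (
                cell.center[0] + dr * (eff_radius + 1),
                cell.center[1] + dc * (eff_radius + 1),
            )
            end = (
                cell.center[0] + dr * (eff_radius + SOMA_RIM + cell.arm_length_px),
                cell.center[1] + dc * (eff_radius + SOMA_RIM + cell.arm_length_px),
            )
            cell_raster |= _rasterize_segment(shape, start, end, cell.arm_width_px)
        cell_raster &= ~nucleus
        nucleus_truth |= nucleus
        microglia_truth |= cell_raster
        nucleus_rasters.append(nucleus)
        cell_rasters.append(cell_raster)
        area = int(nucleus.sum())
        rows_out.append(
            {
                "cell_id": cell_id,
                "class_label": cell.class_label,
                "center_row": cell.center[0],
                "center_col": cell.center[1],
                "nucleus_area_px": area,
                "rel_area_pct": 100.0 * area / image_area,
                "arm_count": cell.arm_count,
            }
        )

    # decoy nuclei: DAPI blobs with no microglial rim (e.g. neuronal nuclei)
    for _ in range(spec.n_decoy_nuclei):
        r = rng.uniform(6, 10)
        margin = int(r) + 2
        cr = int(rng.integers(margin, shape[0] - margin))
        cc = int(rng.integers(margin, shape[1] - margin))
        decoy = _rasterize_disk(shape, (cr, cc), None, r)
        if (decoy & (microglia_truth | nucleus_truth)).any():
            continue  # skip placements that would touch a planted cell
        nucleus_truth |= decoy

    astro_truth = _render_filaments(shape, spec.n_astrocyte_filaments, rng)
    neuro_truth = _render_tracts(shape, spec.n_neurite_tracts, spec.neurite_disorder, rng)

    rasters = {
        "nucleus": nucleus_truth,
        "microglia": microglia_truth,
        "astrocyte": astro_truth,
        "neurofilament": neuro_truth,
    }
    channels = {}
    for label, raster in rasters.items():
        clean = np.where(raster, FOREGROUND, spec.background_level).astype(np.float64)
        channels[label] = _apply_noise(clean, spec, rng)

    truth = SceneTruth(
        cells=pd.DataFrame(
            rows_out,
            columns=[
                "cell_id",
                "class_label",
                "center_row",
                "center_col",
                "nucleus_area_px",
                "rel_area_pct",
                "arm_count",
            ],
        ),
        object_rasters=rasters,
        nucleus_rasters=nucleus_rasters,
        cell_rasters=cell_rasters,
    )
    return SyntheticScene(spec=spec, projection=Projection(channels=channels), truth=truth)


def _render_filaments(shape, n_filaments: int, rng: np.random.Generator) -> np.ndarray:
    """Astrocyte-like filament network: correlated random walks of width 1-2."""
    out = np.zeros(shape, dtype=bool)
    rows, cols = shape
    for _ in range(n_filaments):
        r = rng.uniform(0, rows)
        c = rng.uniform(0, cols)
        theta = rng.uniform(0, 2 * math.pi)
        length = int(rng.integers(60, 140))
        width = float(rng.uniform(1.0, 2.0))
        for _ in range(length):
            theta += rng.normal(0.0, 0.25)
            r2 = r + math.sin(theta) * 2.0
            c2 = c + math.cos(theta) * 2.0
            out |= _rasterize_segment(shape, (r, c), (r2, c2), width)
            r, c = r2, c2
            if not (0 <= r < rows and 0 <= c < cols):
                break
    return out


def _render_tracts(shape, n_tracts: int, disorder: float, rng: np.random.Generator) -> np.ndarray:
    """Neurite tracts: long straight fibers around one base orientation.

    ``disorder`` is the SD (radians) of per-tract orientation; 0 gives the
    parallel arrangement, larger values the irregular one.
    """
    out = np.zeros(shape, dtype=bool)
    rows, cols = shape
    if n_tracts == 0:
        return out
    base = rng.uniform(0, math.pi)
    diag = math.hypot(rows, cols)
    for _ in range(n_tracts):
        theta = base + rng.normal(0.0, disorder)
        mid_r = rng.uniform(0, rows)
        mid_c = rng.uniform(0, cols)
        dr, dc = math.sin(theta), math.cos(theta)
        p0 = (mid_r - dr * diag, mid_c - dc * diag)
        p1 = (mid_r + dr * diag, mid_c + dc * diag)
        out |= _rasterize_segment(shape, p0, p1, float(rng.uniform(1.5, 2.5)))
    return out


def scribbles_for_scene(
    scene: SyntheticScene,
    channel_label: str,
    n_per_class: int = 200,
    seed: int = 0,
    margin_px: int = 2,
):
    """Sample training scribbles from the planted truth of one channel.

    Object scribbles come from the truth raster eroded by ``margin_px``
    (clearly inside structures), background scribbles from outside the
    truth dilated by ``margin_px`` — mimicking how a human marks pixels
    away from fuzzy boundaries.
    """
    from gliascore.segmentation import BACKGROUND as BG_CLASS
    from gliascore.segmentation import OBJECT as OBJ_CLASS
    from gliascore.segmentation import ScribbleSet

    rng = np.random.default_rng(seed)
    truth = scene.truth.object_rasters[channel_label]
    struct = np.ones((3, 3), dtype=bool)
    # thin structures (arms are a few px wide) vanish under a deep erosion:
    # relax the margin until enough core pixels remain to scribble on
    min_core = min(n_per_class, 50)
    core = truth
    for m in range(margin_px, 0, -1):
        eroded = ndimage.binary_erosion(truth, structure=struct, iterations=m)
        if eroded.sum() >= min_core:
            core = eroded
            break
    halo = ~ndimage.binary_dilation(truth, structure=struct, iterations=margin_px)
    entries = []
    for raster, klass in ((core, OBJ_CLASS), (halo, BG_CLASS)):
        coords = np.argwhere(raster)
        if coords.shape[0] == 0:
            raise ValueError(f"no pixels available for class {klass!r}")
        take = rng.choice(coords.shape[0], size=min(n_per_class, coords.shape[0]), replace=False)
        entries.extend((int(r), int(c), klass) for r, c in coords[take])
    return ScribbleSet(entries=entries, channel_label=channel_label)


def random_scene_spec(
    shape: tuple[int, int],
    n_cells: int,
    seed: int,
    *,
    class_labels: list[str] | None = None,
    target_rel_areas_pct: list[float] | None = None,
    nucleus_radius_px: float = 10.0,
    arm_counts: list[int] | None = None,
    arm_length_px: float = DEFAULT_ARM_LENGTH,
    arm_width_px: float = DEFAULT_ARM_WIDTH,
    n_decoy_nuclei: int = 0,
    n_astrocyte_filaments: int = 0,
    n_neurite_tracts: int = 0,
    neurite_disorder: float = 0.0,
    noise_sd_frac: float = 0.05,
) -> SceneSpec:
    """Place ``n_cells`` non-overlapping cells on a jittered grid.

    Grid spacing keeps each cell's full reach (nucleus + rim + arms) from
    touching any neighbour's influence ring, so planted per-cell arm counts
    are recoverable exactly. Raises if the cells do not fit.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    image_area = rows * cols
    if target_rel_areas_pct is not None and len(target_rel_areas_pct) != n_cells:
        raise ValueError("need one target area per cell")
    if class_labels is not None and len(class_labels) != n_cells:
        raise ValueError("need one class label per cell")
    if arm_counts is not None and len(arm_counts) != n_cells:
        raise ValueError("need one arm count per cell")

    radii = []
    for i in range(n_cells):
        if target_rel_areas_pct is not None:
            radii.append(math.sqrt(target_rel_areas_pct[i] / 100.0 * image_area / math.pi))
        else:
            radii.append(nucleus_radius_px)
    max_radius = max(radii, default=nucleus_radius_px)
    ring_reach = DEFAULT_CONFIG.ring_gap_px + DEFAULT_CONFIG.ring_width_px + 1
    reach = max_radius + SOMA_RIM + max(arm_length_px, ring_reach)
    margin = int(math.ceil(reach)) + 1
    spacing = int(math.ceil(2 * reach)) + 2
    jitter = 3

    positions = []
    r = margin + jitter
    while r < rows - margin - jitter:
        c = margin + jitter
        while c < cols - margin - jitter:
            positions.append((r, c))
            c += spacing
        r += spacing
    if len(positions) < n_cells:
        raise ValueError(
            f"cannot place {n_cells} non-overlapping cells in a {shape} image "
            f"(capacity {len(positions)})"
        )
    chosen = rng.choice(len(positions), size=n_cells, replace=False)
    cells = []
    for i, pos_idx in enumerate(chosen):
        pr, pc = positions[pos_idx]
        center = (
            int(pr + rng.integers(-jitter, jitter + 1)),
            int(pc + rng.integers(-jitter, jitter + 1)),
        )
        label = class_labels[i] if class_labels is not None else None
        if arm_counts is not None:
            n_arms = arm_counts[i]
        elif label in CLASS_ARM_COUNTS:
            n_arms = CLASS_ARM_COUNTS[label]
        else:
            n_arms = 4
        if target_rel_areas_pct is not None:
            cells.append(
                CellSpec(
                    center=center,
                    target_rel_area_pct=float(target_rel_areas_pct[i]),
                    arm_count=n_arms,
                    arm_length_px=arm_length_px,
                    arm_width_px=arm_width_px,
                    class_label=label,
                )
            )
        else:
            cells.append(
                CellSpec(
                    center=center,
                    nucleus_radius_px=nucleus_radius_px,
                    arm_count=n_arms,
                    arm_length_px=arm_length_px,
                    arm_width_px=arm_width_px,
                    class_label=label,
                )
            )
    return SceneSpec(
        shape=shape,
        seed=int(rng.integers(0, 2**31 - 1)),
        cells=tuple(cells),
        n_decoy_nuclei=n_decoy_nuclei,
        n_astrocyte_filaments=n_astrocyte_filaments,
        n_neurite_tracts=n_neurite_tracts,
        neurite_disorder=neurite_disorder,
        noise_sd_frac=noise_sd_frac,
    )


def sample_class_areas(
    label: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw class-conditional relative nucleus areas (% of image area).

    Normal with the published class mean; SD back-computed from the printed
    95% CI and n (s = sqrt(n) * (ci_high - mean) / t_{0.975, n-1}).
    """
    n_ref, mean, _, ci_high = REFERENCE_STATE_TABLE[label]
    sd = state_sd_from_ci(n_ref, mean, ci_high)
    draws = rng.normal(mean, sd, size=n)
    # nucleus areas are physical: resample the rare non-positive draws
    while np.any(draws <= 0.02):
        bad = draws <= 0.02
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return draws


def render_zstack(
    scene: SyntheticScene,
    n_planes: int = 30,
    spacing_um: float = 0.24,
    axial_sigma_planes: float = 2.0,
) -> ChannelStack:
    """Spread a scene over Z-planes with per-cell Gaussian axial profiles.

    Each planted cell (and each non-cell channel) peaks at a random plane
    with weight 1, so the maximum-intensity projection of the stack equals
    the clean 2-D scene up to rounding. Planes are rendered noise-free; the
    scene's noise model applies to the 2-D render, not the stack.
    """
    if n_planes < 1:
        raise ValueError("n_planes must be >= 1")
    if spacing_um <= 0:
        raise ValueError("spacing_um must be positive")
    rng = np.random.default_rng(scene.spec.seed + 1)
    bg = scene.spec.background_level
    shape = scene.shape
    planes_idx = np.arange(n_planes)

    def profile(center: int) -> np.ndarray:
        if n_planes == 1:
            return np.ones(1)
        return np.exp(-((planes_idx - center) ** 2) / (2 * axial_sigma_planes**2))

    channels: dict[str, np.ndarray] = {}
    # per-cell axial positions shared between the nucleus and microglia
    # channels (one physical cell, one focal depth)
    cell_centers = rng.integers(0, n_planes, size=len(scene.truth.nucleus_rasters))
    for label in ("nucleus", "microglia"):
        structs = (
            scene.truth.nucleus_rasters
            if label == "nucleus"
            else scene.truth.cell_rasters
        )
        stack = np.zeros((n_planes, *shape), dtype=np.float64)
        for raster, center in zip(structs, cell_centers):
            w = profile(int(center))
            stack = np.maximum(stack, w[:, None, None] * raster * (FOREGROUND - bg))
        # decoy nuclei and anything else in the channel truth but not in a
        # per-cell raster sits at a single random plane
        extra = scene.truth.object_rasters[label].copy()
        for raster in structs:
            extra &= ~raster
        if extra.any():
            w = profile(int(rng.integers(0, n_planes)))
            stack = np.maximum(stack, w[:, None, None] * extra * (FOREGROUND - bg))
        channels[label] = np.clip(np.rint(stack + bg), 0, DYNAMIC_RANGE).astype(np.uint16)
    for label in ("astrocyte", "neurofilament"):
        raster = scene.truth.object_rasters[label]
        w = profile(int(rng.integers(0, n_planes)))
        stack = w[:, None, None] * raster * (FOREGROUND - bg) + bg
        channels[label] = np.clip(np.rint(stack), 0, DYNAMIC_RANGE).astype(np.uint16)
    return ChannelStack(
        channels=channels,
        plane_spacing_um=spacing_um,
        max_planes=max(n_planes, DEFAULT_CONFIG.max_planes),
    )


# ---------------------------------------------------------------------------
# study-level generation


@dataclass(frozen=True)
class StudyDesign:
    """Factorial design of a synthetic study (lines x days x mice x images)."""

    lines: tuple[str, ...] = ("wild_type", "tnf_overexpressing")
    days: tuple[int, ...] = (3, 7, 14)
    n_mice_per_line: int = 6
    images_per_mouse: int = 3
    region: str = "CA3"
    shape: tuple[int, int] = (320, 320)
    n_cells_per_image: int = 4

    def __post_init__(self) -> None:
        if not self.lines or not self.days:
            raise ValueError("design needs at least one line and one day")
        if self.n_mice_per_line < 1 or self.images_per_mouse < 1:
            raise ValueError("design needs at least one mouse and one image")
        if self.n_mice_per_line > 9:
            raise ValueError("at most 9 mice per group")


@dataclass(frozen=True)
class StudyEffect:
    """Planted per-line multipliers applied to the transgenic line."""

    arm_count_ratio: float = 1.0  # e.g. 0.5 halves mean process counts
    cell_count_ratio: float = 1.0
    nucleus_area_ratio: float = 1.0


def generate_study(
    design: StudyDesign,
    effect: StudyEffect = StudyEffect(),
    seed: int = 0,
    *,
    class_mixture: dict[str, float] | None = None,
    return_scenes: bool = False,
):
    """Render a full synthetic study and measure it through the pipeline.

    For each image, a scene is generated with per-cell classes drawn from
    ``class_mixture`` (default: the published calibration proportions),
    class-conditional nucleus areas, and per-class arm counts; the
    transgenic line's parameters are scaled by the planted effect. The
    scene is then measured with the nucleus and ring modules (using the
    planted object rasters as masks) to produce a tidy per-image study
    frame with metrics: microglia_count, mean_process_count,
    microglia_area_fraction, mean_nucleus_rel_area.

    Returns ``(frame, truth_frame)`` or ``(frame, truth_frame, scenes)``.
    """
    from gliascore.nuclei import detect_nuclei
    from gliascore.ring_morphometry import mean_process_count, score_microglia
    from gliascore.segmentation import SegmentationMask, area_fraction

    if class_mixture is None:
        total = sum(n for n, *_ in REFERENCE_STATE_TABLE.values())
        class_mixture = {
            label: n / total for label, (n, *_) in REFERENCE_STATE_TABLE.items()
        }
    labels = list(class_mixture)
    probs = np.array([class_mixture[k] for k in labels], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    rows_out = []
    truth_rows = []
    scenes = {}
    image_area = design.shape[0] * design.shape[1]
    for line in design.lines:
        transgenic = line != "wild_type"
        for day in design.days:
            for mouse_i in range(design.n_mice_per_line):
                mouse = f"{line}_m{mouse_i}"
                for image_i in range(design.images_per_mouse):
                    n_cells = design.n_cells_per_image
                    if transgenic and effect.cell_count_ratio != 1.0:
                        n_cells = max(1, int(round(n_cells * effect.cell_count_ratio)))
                    cell_labels = [
                        labels[i] for i in rng.choice(len(labels), size=n_cells, p=probs)
                    ]
                    areas = np.concatenate(
                        [sample_class_areas(lbl, 1, rng) for lbl in cell_labels]
                    )
                    if transgenic:
                        areas = areas * effect.nucleus_area_ratio
                    # floor at a detectable nucleus size: blobs below the
                    # background threshold are not nuclei by definition
                    areas = np.maximum(areas, 100.0 * 32 / image_area)
                    arm_counts = []
                    for lbl in cell_labels:
                        lam = CLASS_ARM_COUNTS[lbl]
                        if transgenic:
                            lam = lam * effect.arm_count_ratio
                        arm_counts.append(int(rng.poisson(lam)))
                    spec = random_scene_spec(
                        design.shape,
                        n_cells,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        class_labels=cell_labels,
                        target_rel_areas_pct=list(areas),
                        arm_counts=arm_counts,
                    )
                    scene = generate_scene(spec)
                    image_id = f"{mouse}_d{day}_i{image_i}"
                    if return_scenes:
                        scenes[image_id] = scene

                    nuc_mask = SegmentationMask(
                        scene.truth.object_rasters["nucleus"], "nucleus", 24
                    )
                    mg_mask = SegmentationMask(
                        scene.truth.object_rasters["microglia"], "microglia", 24
                    )
                    records = detect_nuclei(scene.projection, nuc_mask, mg_mask)
                    scored = score_microglia(scene.projection, records, mg_mask)
                    metrics = {
                        "microglia_count": float(len(records)),
                        "microglia_area_fraction": area_fraction(mg_mask),
                        "mean_process_count": (
                            mean_process_count(scored) if scored else 0.0
                        ),
                        "mean_nucleus_rel_area": (
                            float(np.mean([r.relative_area_pct for r in records]))
                            if records
                            else 0.0
                        ),
                    }
                    for metric, value in metrics.items():
                        rows_out.append(
                            {
                                "mouse": mouse,
                                "line": line,
                                "day": day,
                                "region": design.region,
                                "metric": metric,
                                "value": value,
                                "image": image_id,
                            }
                        )
                    truth_rows.append(
                        {
                            "image": image_id,
                            "mouse": mouse,
                            "line": line,
                            "day": day,
                            "n_cells": n_cells,
                            "mean_arm_count": float(np.mean(arm_counts)) if arm_counts else 0.0,
                            "mean_rel_area": float(np.mean(areas)),
                        }
                    )
    frame = pd.DataFrame(rows_out)
    truth_frame = pd.DataFrame(truth_rows)
    if return_scenes:
        return frame, truth_frame, scenes
    return frame, truth_frame
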