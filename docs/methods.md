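# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic validation does and does not
demonstrate.

## Image model and projection

Input is a registered multi-channel Z-stack, one channel per stain
(DAPI → `nucleus`, Iba1 → `microglia`, GFAP → `astrocyte`, neurofilament →
`neurofilament`). Stain display colors are treated as presentation only;
channels are stored as separate named rasters, row-major, origin top-left,
16-bit unsigned (8-bit input is up-scaled by 257). Stacks are capped at a
configurable 30 planes with 0.24 µm default spacing — the workflow's
expected acquisition envelope, kept configurable because acquisition depth
varies between slides.

The maximum-intensity projection keeps every structure at its brightest
focal plane and is the raster all downstream measurement runs on. It is
permutation-invariant over planes and idempotent; both properties are
asserted in tests.

## Pixel classification

Trainable segmentation uses a per-pixel feature bank: raw intensity,
Gaussian-smoothed intensity at σ = 1, 2 and 4 px, Sobel gradient
magnitude, and local variance in a 5×5 window. The bank is a compact
stand-in for the feature sets of interactive trainable-segmentation tools;
it is versioned (`FEATURE_RECIPE`) and recorded in each trained model so
that training/prediction mismatches fail loudly rather than silently.

The decision function is a seeded, single-threaded random forest
(50 trees, depth ≤ 12). Any deterministic discriminative classifier would
satisfy the contract; the forest was chosen because it handles the small,
user-scribbled training sets (hundreds of pixels) without feature scaling
and reproduces masks bit-exactly for a fixed seed — a reproducibility
property the tests assert.

Background suppression removes 8-connected components strictly smaller
than `min_object_size` (default 24 px). Two conventions are deliberate:
8-connectivity, because diagonally touching fluorescent pixels belong to
one structure, and strictly-below removal, so a component of exactly the
threshold size survives. An alternative, more aggressive threshold
(&lt; 150 px) is known from related workflows; it is reachable through the
same configuration knob but is not the default.

## Nucleus detection

A DAPI component is accepted as a microglial nucleus when at least
`border_fraction_min` (default 0.5) of its one-pixel outward dilation
shell is covered by Iba1 object pixels. The published criterion is
qualitative ("a green border around the nucleus"); 50% coverage is the
explicit operational default and is configurable because the original
workflow does not state whether a full or partial ring was required.
Candidates below the shared 24-px background threshold are discarded
before the border test, for consistency with the global background rule.

Touching nuclei are split by a distance-transform watershed before the
border test. The distance surface is smoothed (σ = 2 px) before peak
detection with a 7-px minimum peak separation so that boundary roughness
from noisy segmentation does not fragment a single nucleus; split records
carry a flag. Elongated nuclei (eccentricity > 0.95) are flagged as
rod-cell candidates as metadata only — they are not a class in the
activity classifier.

## Influence-zone ring and process counting

The ring around a nucleus is defined on integer distance shells: pixel `p`
belongs to shell `⌊d(p, N)⌋`, the floor of its Euclidean distance to the
nucleus pixel set, and the ring collects shells `gap+1 … gap+width`
(defaults 9 and 14). This makes the gap exactly nine one-pixel layers of
background and the ring fourteen layers, which is what a distance-transform
measurement on a planted disk nucleus returns: minimum ring distance 10
(open gap 9), max−min spread ≈ 14. An isotropic Euclidean metric is the
default; a chessboard variant (square rings) is selectable for users who
want parity with chamfer-based tools.

Processes are the 8-connected components of (Iba1 mask ∩ ring). A process
that leaves the ring and re-enters counts once per crossing — contiguity
is evaluated within the ring subgraph, matching the definition that green
runs separated by black pixels are separate processes. The nucleus's own
pixels are subtracted from the counting mask so a lobulated soma cannot
count as its own process. Signal from a neighboring cell inside the ring
*is* counted (the method defines no ownership test), but overlapping rings
are flagged so users can filter ambiguous cells; rings clipped by the
image border are likewise flagged.

## Activity-state classifier

Per state, the mean relative nucleus area (percent of total image area,
per cell) and a two-sided 95% t-interval are fitted; an all-equal sample
yields the degenerate interval [c, c]. States with overlapping intervals
are merged by transitive closure; group boundaries sit at the midpoint of
the gap between adjacent effective intervals, with midpoint ties broken
toward the lower group and out-of-range values clamped to the extreme
groups (the calibration gives upper and lower limits but no out-of-range
rule, so clamping is this package's choice).

The built-in calibration table (n, mean, 95% CI per state over 197
visually staged cells) reproduces the published structure: ramified
[0.15, 0.25] and hyper-ramified [0.15, 0.18] overlap and merge; bushy
[0.39, 0.44] and amoeboid [0.59, 0.81] stay separate — three groups, with
boundaries at 0.32 and 0.515. The per-cell reading of "relative nucleus
area" is adopted throughout; averaging per image is known to blur class
structure, which is exactly why the classifier operates per cell.

Separation of labeled states is validated with a Kruskal–Wallis test plus
all pairwise two-sided Mann–Whitney tests, reported raw and Holm-adjusted.

## Study statistics

Per-image metrics are averaged per mouse within (day, region) — the mouse
is the experimental unit. Group comparisons use a Shapiro–Wilk gate at
α = 0.05 per group; if either group is non-normal, both are natural-log
transformed and re-tested, and the two-sample test runs on the transformed
values. The two-sample test is Welch's t-test: the original analysis names
no specific parametric test, and unequal variances between a wild-type and
a transgenic line are plausible, so the variance-robust choice is made
here. Multi-day comparisons report raw p-values (matching the original
presentation, which states no correction) alongside Holm-adjusted ones.
Null simulations at n = 8 mice per group place the procedure's type-I
error within [0.03, 0.07] at nominal 0.05 (asserted over 1,000
replicates).

## Synthetic scenes

The generator emulates the structures the pipeline must measure, with
ground truth recorded before noise:

- **nuclei**: rasterized disks; when a target relative area is given, the
  disk radius is tuned over complete distance shells so the pixel count
  matches the target almost exactly (sub-pixel-percent error);
- **microglia**: a 3-px soma rim hugging the nucleus boundary (which
  guarantees the green-border criterion) plus straight radial arms of
  default length 28 px and width 3 px at evenly spaced, jittered angles —
  straight arms make the ring-crossing count analytically equal to the arm
  count, which is what the exactness tests rely on; curvature is a later
  extension;
- **decoy nuclei**: DAPI blobs without a rim, to exercise the border
  criterion's specificity;
- **astrocytes**: correlated random-walk filaments; **neurites**: long
  straight tracts around one base orientation with a disorder parameter
  (SD of per-tract angle), 0 giving the parallel wild-type-like
  arrangement;
- **intensity model**: background 3000, foreground 46000 on the 16-bit
  scale; additive Gaussian noise with SD = 5% of the dynamic range
  (optional Poisson), applied last. At this noise level the trained
  segmentation reaches ≥ 0.95 pixel agreement with the planted rasters,
  which is the regime the recovery tests are calibrated to.

Class-conditional nucleus areas are drawn as normal with the calibration
means and SDs back-computed from the printed CIs,
`s = √n · (ci_high − mean) / t₀.₉₇₅,ₙ₋₁`; draws below 0.02% of image area
(far tails) are resampled, since a nucleus below the background threshold
is not a nucleus. Cells are placed on a jittered grid whose spacing keeps
every cell's full reach (nucleus + rim + arms) clear of its neighbours'
rings, so planted counts are recoverable exactly; the generator raises
rather than overpacking. Because per-cell relative area fixes the nucleus
radius as a fraction of image size, large per-class cohorts (e.g. 68 cells
at 0.41%) physically cannot fit one frame and are distributed across
several same-shape images.

Z-stacks place each cell's axial Gaussian profile (σ = 2 planes) at a
random plane with peak weight 1, so the maximum projection of a rendered
stack equals the clean 2-D scene to within one intensity unit (asserted as
a round-trip test); stack planes are rendered noise-free, with the noise
model belonging to the 2-D render.

Scribbles for training are sampled from the planted truth, eroded so they
sit clearly inside structures; the erosion margin relaxes automatically
for thin structures (a 3-px arm erodes away at margin 2), mimicking a
human scribbling along a thin process's centerline.

**What passing on synthetic scenes does not show:** real tissue has
overlapping and curved processes, intensity inhomogeneity, out-of-focus
haze, touching cells in clusters larger than two, and anisotropic PSF
blur — none of which the generator models. Recovery results here certify
the measurement logic (geometry, counting, thresholds, statistics), not
robustness to acquisition artifacts.

## Problem sizes and determinism

All randomness flows through seeded `numpy` generators; identical spec and
seed give bit-identical scenes, masks and statistics. The validation suite
uses 512×512 scenes for geometry checks, 100 random scenes for arm-count
exactness, 50 for nucleus-count exactness, 1,000 replicates for type-I
calibration, and 12 × 13 amoeboid plus 4 × 68 bushy planted cells for
class-mean recovery — sizes chosen so the whole suite certifies each claim
with comfortable Monte-Carlo margins while remaining quick to run on a
laptop.

## Known limitations

- Astrocytes are measured only as an area fraction; their dense network is
  not separable into single cells with this pipeline's primitives.
- Process counts are 2-D: processes crossing the ring only in planes the
  projection merges are counted once, and processes missed by all planes
  are not counted at all.
- The ring does not attribute processes to owners; dense fields should be
  filtered on the overlap flag.
- Physical units: all thresholds are in pixels; no µm calibration is
  applied to measurements (pixel size is carried as metadata only).
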