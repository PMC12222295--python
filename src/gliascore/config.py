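"""Shared pipeline defaults.

The defaults are the operating point of the published workflow: background
pixel groups smaller than 24 px are suppressed, the process-counting ring
sits 9 px outside the nucleus boundary and is 14 px wide, and a nucleus
candidate counts as microglial when at least half of its one-pixel outer
shell is covered by microglia-channel signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs shared across pipeline stages.

    Attributes
    ----------
    min_object_size_px:
        Connected components (8-neighborhood) strictly smaller than this are
        treated as background noise in every channel, including nucleus
        candidates. 24 px is the workflow's calibrated background threshold.
    ring_gap_px:
        Number of one-pixel distance shells between the nucleus boundary and
        the inner edge of the zone-of-influence ring.
    ring_width_px:
        Number of one-pixel distance shells the ring spans.
    border_fraction_min:
        Minimum fraction of the nucleus's 1-px outward dilation shell that
        must be microglia-channel object for the nucleus to be accepted as
        microglial. The published criterion is qualitative ("a green border
        around the nucleus"); 0.5 is the explicit operational default.
    ring_metric:
        Distance metric for the ring shells. "euclidean" (isotropic) is the
        default; "chessboard" selects the 8-neighborhood chamfer variant.
    max_planes:
        Upper bound on Z-planes accepted per stack (stacks of up to 30
        planes are the expected input).
    plane_spacing_um:
        Default axial spacing between Z-planes, in micrometres.
    """

    min_object_size_px: int = 24
    ring_gap_px: int = 9
    ring_width_px: int = 14
    border_fraction_min: float = 0.5
    ring_metric: Literal["euclidean", "chessboard"] = "euclidean"
    max_planes: int = 30
    plane_spacing_um: float = 0.24
    split_touching_nuclei: bool = True

    def __post_init__(self) -> None:
        if self.min_object_size_px < 0:
            raise ValueError("min_object_size_px must be non-negative")
        if self.ring_gap_px < 0:
            raise ValueError("ring_gap_px must be non-negative")
        if self.ring_width_px < 1:
            raise ValueError("ring_width_px must be >= 1")
        if not 0.0 <= self.border_fraction_min <= 1.0:
            raise ValueError("border_fraction_min must lie in [0, 1]")
        if self.max_planes < 1:
            raise ValueError("max_planes must be >= 1")
        if self.plane_spacing_um <= 0:
            raise ValueError("plane_spacing_um must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = PipelineConfig()
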