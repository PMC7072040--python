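"""Pipeline configuration.

Every constant of the screening protocol is a named key here rather than a
literal in the code: the positioning-error exclusion threshold (0.5), the
final suspiciousness cut-off (0.999), the cut-off sweep list, the assumed
population prevalence (5.9%) and the hypothetical-population size (10,000).
Geometric parameters (mid-spine bump width, smoothing penalty, positioning
normalisers) are expressed at the standard working height and rescaled
internally for other image sizes.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .errors import InvalidInputError

#: Working height (rows) every scan is standardised to before analysis.
DEFAULT_TARGET_HEIGHT_PX = 512

#: Cut-offs of the suspiciousness score examined by the sweep.
DEFAULT_CUTOFFS = (0.95, 0.98, 0.99, 0.995, 0.999, 0.9995)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the screening pipeline."""

    # preprocessing
    target_height_px: int = DEFAULT_TARGET_HEIGHT_PX

    # anatomy / mid-spine map (pixel units at target_height_px)
    midspine_sigma_px: float = 3.0
    spine_band_halfwidth_px: float = 5.0
    ridge_track_halfwidth_px: float = 6.0
    #: ridge contrast below this fraction of the seed-row contrast ends the spine
    ridge_stop_fraction: float = 0.35

    # midline smoothing / curvature
    midline_smoothing_lam: float = 1000.0
    tangent_trim_fraction: float = 0.02

    # suspiciousness calibration (logistic in the measured angle)
    score_midpoint_deg: float = 6.0
    score_steepness_per_deg: float = 1.5

    # positioning-error normalisers and exclusion rule
    tilt_max_deg: float = 10.0
    offset_max_frac: float = 0.15  # of image width
    asym_max: float = 0.2
    positioning_exclusion_threshold: float = 0.5

    # binary decision and population projection
    cutoff: float = 0.999
    sweep_cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS
    prevalence: float = 0.059
    projection_n: int = 10_000

    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_height_px < 2:
            raise InvalidInputError("target_height_px must be >= 2")
        if not 0.0 <= self.cutoff <= 1.0:
            raise InvalidInputError("cutoff must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise InvalidInputError("prevalence must lie in (0, 1)")
        if list(self.sweep_cutoffs) != sorted(set(self.sweep_cutoffs)):
            raise InvalidInputError("sweep_cutoffs must be strictly increasing")
        if not all(0.0 <= c <= 1.0 for c in self.sweep_cutoffs):
            raise InvalidInputError("sweep_cutoffs must lie in [0, 1]")

    def with_(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sweep_cutoffs"] = list(self.sweep_cutoffs)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "sweep_cutoffs" in data:
            data["sweep_cutoffs"] = tuple(data["sweep_cutoffs"])
        return cls(**data)

    def scale(self, height_px: int) -> float:
        """Pixel-unit scale factor for an image of ``height_px`` rows."""
        return height_px / float(DEFAULT_TARGET_HEIGHT_PX)
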