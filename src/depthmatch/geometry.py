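"""Stimulus geometry and photometry utilities.

Covers the two size regimes of the depth-matching experiments (constant
visual angle vs. constant physical size) and the Michelson-contrast
quantification of occluder opacity.  Angles are degrees, sizes and
distances meters, luminances cd/m^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "StimulusSpec",
    "visual_angle_deg",
    "physical_size_for_angle",
    "michelson_contrast",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as printed stimulus values are reported."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def visual_angle_deg(physical_size: float, distance: float) -> float:
    """Visual angle (degrees) subtended by an object of ``physical_size`` meters at ``distance`` meters.

    Uses the exact 2*atan(s / 2d) form rather than the small-angle
    approximation, which matters at near viewing distances.
    """
    if not distance > 0:
        raise ValueError("distance must be strictly positive")
    if physical_size < 0:
        raise ValueError("physical_size must be nonnegative")
    return math.degrees(2.0 * math.atan(physical_size / (2.0 * distance)))


def physical_size_for_angle(angular_size: float, distance: float) -> float:
    """Physical size (meters) subtending ``angular_size`` degrees at ``distance`` meters."""
    if not distance > 0:
        raise ValueError("distance must be strictly positive")
    if not 0.0 < angular_size < 180.0:
        raise ValueError("angular_size must lie in (0, 180) degrees")
    return 2.0 * distance * math.tan(math.radians(angular_size) / 2.0)


def michelson_contrast(l_max: float, l_min: float) -> float:
    """Michelson contrast (l_max - l_min) / (l_max + l_min), in [0, 1]."""
    if l_min < 0:
        raise ValueError("luminances must be nonnegative")
    if l_min > l_max:
        raise ValueError("l_max must be at least l_min")
    if l_max + l_min <= 0:
        raise ValueError("at least one luminance must be positive")
    return (l_max - l_min) / (l_max + l_min)


@dataclass(frozen=True)
class StimulusSpec:
    """Size regime of the virtual target.

    ``constant_angle`` holds the visual angle fixed across distance by
    rescaling the physical letter (the angle-controlled experiment);
    ``constant_physical`` holds the physical size fixed so the angle shrinks
    with distance.  Exactly one of ``angular_size_deg`` / ``physical_size_m``
    controls, depending on the mode.
    """

    size_mode: str
    angular_size_deg: float | None = None
    physical_size_m: float | None = None

    def __post_init__(self) -> None:
        if self.size_mode not in ("constant_angle", "constant_physical"):
            raise ValueError("size_mode must be 'constant_angle' or 'constant_physical'")
        if self.size_mode == "constant_angle":
            if self.angular_size_deg is None or not 0 < self.angular_size_deg < 180:
                raise ValueError("constant_angle mode requires angular_size_deg in (0, 180)")
        else:
            if self.physical_size_m is None or not self.physical_size_m > 0:
                raise ValueError("constant_physical mode requires a positive physical_size_m")

    def physical_size_at(self, distance: float) -> float:
        """Physical size (m) presented at ``distance``."""
        if self.size_mode == "constant_angle":
            return physical_size_for_angle(self.angular_size_deg, distance)
        return self.physical_size_m

    def visual_angle_at(self, distance: float) -> float:
        """Visual angle (degrees) subtended at ``distance``."""
        if self.size_mode == "constant_angle":
            return self.angular_size_deg
        return visual_angle_deg(self.physical_size_m, distance)
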