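"""Screen and viewing geometry.

The accuracy of a gaze tracker is reported in degrees of visual angle so
that it is independent of the screen resolution and of the viewing
distance.  For a flat screen viewed frontally from distance ``D`` an
on-screen distance ``d`` (cm) subtends ``theta = atan(d / D)``.  Pixel
errors are converted through the physical pixel pitch of the monitor,
derived from its diagonal size and resolution (a 4:3 screen at 4:3 pixel
resolution has square pixels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["ScreenGeometry"]


@dataclass(frozen=True)
class ScreenGeometry:
    """Monitor resolution, physical size and viewing distance.

    Defaults describe a 17-inch 1024x768 4:3 monitor viewed from 70 cm.
    """

    width_px: int = 1024
    height_px: int = 768
    diagonal_cm: float = 17.0 * 2.54
    viewing_distance_cm: float = 70.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen resolution must be positive")
        if self.diagonal_cm <= 0 or self.viewing_distance_cm <= 0:
            raise ValueError("screen size and viewing distance must be positive")

    @property
    def pixel_pitch_cm(self) -> float:
        """Physical size of one (square) pixel in cm."""
        return self.diagonal_cm / math.hypot(self.width_px, self.height_px)

    def pixels_to_degrees(self, e_px: float) -> float:
        """Visual angle (degrees) subtended by an on-screen distance in pixels."""
        if e_px < 0:
            raise ValueError("pixel distance must be non-negative")
        return math.degrees(
            math.atan(e_px * self.pixel_pitch_cm / self.viewing_distance_cm)
        )

    def degrees_to_pixels(self, theta_deg: float) -> float:
        """Inverse of :meth:`pixels_to_degrees`."""
        if theta_deg < 0:
            raise ValueError("angle must be non-negative")
        return (
            math.tan(math.radians(theta_deg))
            * self.viewing_distance_cm
            / self.pixel_pitch_cm
        )

    @property
    def center(self) -> tuple[float, float]:
        return (self.width_px / 2.0, self.height_px / 2.0)

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width_px - 1 and 0 <= y <= self.height_px - 1
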