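"""Screen geometry and visual-angle conversions.

All spatial quantities downstream are expressed in degrees of visual angle,
with the origin at the screen center, x increasing rightward and y upward.
Conversion from physical extent to degrees uses the linear small-angle
approximation ``theta = (s / d) * 180 / pi``, which is the convention used to
derive the display calibration constants below (e.g. a 50.9 cm wide screen at
40 cm subtends 72.91 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "InvalidGeometryError",
    "ScreenGeometry",
    "DEFAULT_SCREEN",
    "to_degrees",
]


class InvalidGeometryError(ValueError):
    """Raised when a screen geometry has non-positive physical dimensions."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry of the touchscreen setup.

    Defaults describe a 23-inch 1920 x 1080 touchscreen (50.9 x 28.7 cm)
    viewed from a 40 cm chin rest.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_cm: float = 50.9
    height_cm: float = 28.7
    viewing_distance_cm: float = 40.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm",
                     "viewing_distance_cm"):
            if not getattr(self, name) > 0:
                raise InvalidGeometryError(f"{name} must be > 0")
        if not math.isfinite(self.deg_per_cm):
            raise InvalidGeometryError("degrees-per-cm conversion is not finite")

    @property
    def cm_per_px_x(self) -> float:
        return self.width_cm / self.width_px

    @property
    def cm_per_px_y(self) -> float:
        return self.height_cm / self.height_px

    @property
    def deg_per_cm(self) -> float:
        return (1.0 / self.viewing_distance_cm) * (180.0 / math.pi)

    def cm_to_deg(self, extent_cm: float) -> float:
        """Convert a physical extent in cm to degrees of visual angle."""
        if extent_cm < 0:
            raise ValueError("extent must be >= 0")
        return extent_cm * self.deg_per_cm

    def px_to_deg(self, extent_px: float, axis: str = "x") -> float:
        """Convert a pixel extent to degrees via the screen's pixel pitch."""
        pitch = self.cm_per_px_x if axis == "x" else self.cm_per_px_y
        return self.cm_to_deg(extent_px * pitch)


DEFAULT_SCREEN = ScreenGeometry()


def to_degrees(extent: float, geometry: ScreenGeometry = DEFAULT_SCREEN,
               units: str = "cm", axis: str = "x") -> float:
    """Convert an extent (cm or px) on a screen to degrees of visual angle.

    Parameters
    ----------
    extent
        Non-negative extent in the given units.
    geometry
        Screen geometry supplying pixel pitch and viewing distance.
    units
        ``"cm"`` or ``"px"``.
    axis
        Pixel pitch axis (``"x"`` or ``"y"``); ignored for cm inputs.
    """
    if units == "cm":
        return geometry.cm_to_deg(extent)
    if units == "px":
        return geometry.px_to_deg(extent, axis=axis)
    raise ValueError(f"unknown units {units!r}")
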