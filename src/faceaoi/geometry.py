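"""Pixel / centimetre / degree-of-visual-angle conversions for a flat screen.

The observer is assumed to view the screen frontally at a fixed distance.
All conversions use the tangent-exact formula

    angle = 2 * atan(extent_cm / (2 * distance_cm))

rather than the small-angle approximation; the two agree to well under 0.1%
for extents much smaller than the viewing distance, but only the exact form
reproduces the angular size of the full screen.

Off-center extents are converted with the same centered formula; the
eccentricity correction is ignored, which is a good approximation for the
central region of a desktop display where a face stimulus sits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

HORIZONTAL = "horizontal"
VERTICAL = "vertical"


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical and pixel geometry of the display plus viewing distance.

    Parameters
    ----------
    width_px, height_px
        Screen resolution in pixels.
    width_cm, height_cm
        Physical size of the display area in centimetres.
    distance_cm
        Eye-to-screen distance in centimetres.
    """

    width_px: int
    height_px: int
    width_cm: float
    height_cm: float
    distance_cm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm", "distance_cm"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise DomainError(f"{name} must be positive and finite, got {value!r}")

    def pitch_cm_per_px(self, axis: str) -> float:
        """Physical size of one pixel along ``axis`` in cm."""
        if axis == HORIZONTAL:
            return self.width_cm / self.width_px
        if axis == VERTICAL:
            return self.height_cm / self.height_px
        raise DomainError(f"axis must be {HORIZONTAL!r} or {VERTICAL!r}, got {axis!r}")

    def extent_deg(self, axis: str) -> float:
        """Angular extent of the full screen along ``axis`` in degrees."""
        cm = self.width_cm if axis == HORIZONTAL else self.height_cm
        return math.degrees(2.0 * math.atan2(cm, 2.0 * self.distance_cm))


def infer_distance(extent_cm: float, extent_deg: float) -> float:
    """Viewing distance (cm) at which ``extent_cm`` subtends ``extent_deg``.

    Solves ``2*atan(extent_cm / (2*d)) = extent_deg`` for ``d`` in closed form:
    ``d = (extent_cm / 2) / tan(extent_deg / 2)``.
    """
    if not (extent_cm > 0):
        raise DomainError(f"extent_cm must be > 0, got {extent_cm!r}")
    if not (0.0 < extent_deg < 180.0):
        raise DomainError(f"extent_deg must lie in (0, 180), got {extent_deg!r}")
    return (extent_cm / 2.0) / math.tan(math.radians(extent_deg) / 2.0)


def px_to_deg(n_px, geom: ScreenGeometry, axis: str = HORIZONTAL):
    """Convert a pixel extent to degrees of visual angle.

    Odd function of ``n_px``; accepts scalars or arrays.
    """
    pitch = geom.pitch_cm_per_px(axis)
    cm = np.asarray(n_px, dtype=float) * pitch
    deg = np.degrees(2.0 * np.arctan2(cm, 2.0 * geom.distance_cm))
    if np.ndim(n_px) == 0:
        return float(deg)
    return deg


def deg_to_px(angle_deg, geom: ScreenGeometry, axis: str = HORIZONTAL):
    """Convert degrees of visual angle to a pixel extent (inverse of px_to_deg)."""
    angle = np.asarray(angle_deg, dtype=float)
    if np.any(np.abs(angle) >= 180.0):
        raise DomainError("angle_deg must satisfy |angle| < 180")
    pitch = geom.pitch_cm_per_px(axis)
    px = 2.0 * geom.distance_cm * np.tan(np.radians(angle) / 2.0) / pitch
    if np.ndim(angle_deg) == 0:
        return float(px)
    return px


def study_screen() -> ScreenGeometry:
    """Geometry of a 22-inch 1680x1050 display (47.38 x 29.61 cm).

    The viewing distance is not an independent input: it is inferred from the
    screen width and its 32.61 degree horizontal angular extent, which puts
    the observer at roughly 81 cm.  Treat it as a reconstruction consistent
    with the printed numbers, not a measured quantity.
    """
    distance = infer_distance(47.38, 32.61)
    return ScreenGeometry(
        width_px=1680, height_px=1050, width_cm=47.38, height_cm=29.61,
        distance_cm=distance,
    )
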