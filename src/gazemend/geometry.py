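"""Screen and viewing geometry, and degree <-> pixel conversions.

All angular quantities are in degrees, all on-screen quantities in pixels,
and all velocities in per-millisecond units (the natural unit at a 1000 Hz
sampling rate, where one sample period is 1 ms).

The conversion is evaluated at the screen centre: one degree of visual
angle subtends ``distance * tan(1 deg)`` metres there, which the pixel
pitch turns into pixels. Eccentricity-dependent (per-sample) corrections
are deliberately not applied -- the velocity threshold this package uses
is a single global constant, and the difference is far below the
tracker's accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ScreenGeometry",
    "DEFAULT_GEOMETRY",
    "px_per_degree",
    "deg_per_ms_to_px_per_ms",
    "px_per_ms_to_deg_per_ms",
    "angular_extent",
]


class GeometryError(ValueError):
    """Raised for invalid screen/viewing geometry."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Pixel grid, physical screen size and viewing distance.

    Parameters
    ----------
    width_px, height_px
        Screen resolution in pixels.
    width_m, height_m
        Physical screen size in metres.
    viewing_distance_m
        Optical path length from the eye to the screen in metres (for a
        scanner-bore mirror setup this is the mirror path, not the
        line-of-sight distance).
    """

    width_px: int
    height_px: int
    width_m: float
    height_m: float
    viewing_distance_m: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_m", "height_m", "viewing_distance_m"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be strictly positive, got {getattr(self, name)!r}")

    @property
    def pixel_pitch_m(self) -> float:
        """Horizontal pixel pitch (metres per pixel)."""
        return self.width_m / self.width_px

    @property
    def pixel_pitch_y_m(self) -> float:
        return self.height_m / self.height_px

    def is_square_pixel(self, rel_tol: float = 0.01) -> bool:
        """Whether horizontal and vertical pixel pitch agree within ``rel_tol``."""
        return math.isclose(self.pixel_pitch_m, self.pixel_pitch_y_m, rel_tol=rel_tol)


#: Default geometry: 1680x1050 px viewed at 1 m. The physical width is not a
#: measured quantity; 0.6604 m is back-derived so that the saccade-speed
#: ceiling of 0.9 deg/ms converts to 40 px/ms, and 0.4128 m keeps pixels
#: square. Override from config for a real display.
DEFAULT_GEOMETRY = ScreenGeometry(
    width_px=1680,
    height_px=1050,
    width_m=0.6604,
    height_m=0.4128,
    viewing_distance_m=1.0,
)


def px_per_degree(geom: ScreenGeometry) -> float:
    """Pixels subtended by 1 degree of visual angle at screen centre.

    Computed by exact trigonometry along the horizontal axis:
    ``distance * tan(1 deg) / pixel_pitch``.
    """
    return geom.viewing_distance_m * math.tan(math.radians(1.0)) / geom.pixel_pitch_m


def deg_per_ms_to_px_per_ms(v_deg_per_ms: float, geom: ScreenGeometry = DEFAULT_GEOMETRY) -> float:
    """Convert an angular speed (deg/ms) to an on-screen speed (px/ms).

    Raises
    ------
    GeometryError
        If ``v_deg_per_ms`` is negative (speeds are magnitudes).
    """
    if v_deg_per_ms < 0:
        raise GeometryError(f"speed must be non-negative, got {v_deg_per_ms!r}")
    return v_deg_per_ms * px_per_degree(geom)


def px_per_ms_to_deg_per_ms(v_px_per_ms: float, geom: ScreenGeometry = DEFAULT_GEOMETRY) -> float:
    """Inverse of :func:`deg_per_ms_to_px_per_ms`."""
    if v_px_per_ms < 0:
        raise GeometryError(f"speed must be non-negative, got {v_px_per_ms!r}")
    return v_px_per_ms / px_per_degree(geom)


def angular_extent(geom: ScreenGeometry) -> tuple[float, float]:
    """Full-screen subtended visual angle (width_deg, height_deg).

    Uses the exact ``2*atan(size / 2 / distance)`` form per axis, so the
    extent saturates correctly for screens large relative to the viewing
    distance.
    """
    d = geom.viewing_distance_m
    w = 2.0 * math.degrees(math.atan(geom.width_m / 2.0 / d))
    h = 2.0 * math.degrees(math.atan(geom.height_m / 2.0 / d))
    return w, h
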