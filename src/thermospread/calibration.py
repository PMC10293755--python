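"""Pixel-to-millimetre calibration from an in-scene fiducial of known length.

A single scalar scale is used: pixels are assumed square and uniform (no
lens-distortion or perspective correction).  Fiducial endpoints are given in
pixel coordinates (row, col), pixel centers, 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateFiducialError

__all__ = ["CalibrationResult", "compute_pixel_size", "scaled_area"]

PixelPoint = tuple[float, float]


@dataclass(frozen=True)
class CalibrationResult:
    """mm-per-pixel scale derived from a fiducial of known physical length."""

    mm_per_pixel: float
    fiducial_p1: PixelPoint | None = None
    fiducial_p2: PixelPoint | None = None
    known_length_mm: float | None = None

    def __post_init__(self) -> None:
        if not (self.mm_per_pixel > 0):
            raise ValueError(f"mm_per_pixel must be positive, got {self.mm_per_pixel}")

    @property
    def pixel_area_mm2(self) -> float:
        return self.mm_per_pixel**2


def compute_pixel_size(
    p1: PixelPoint, p2: PixelPoint, known_length_mm: float
) -> CalibrationResult:
    """Derive the pixel scale from two fiducial endpoints.

    ``mm_per_pixel = known_length_mm / ||p2 - p1||`` with the Euclidean pixel
    distance; raises on coincident endpoints or non-positive length.
    """
    if known_length_mm <= 0:
        raise ValueError(f"known_length_mm must be positive, got {known_length_mm}")
    dr = float(p2[0]) - float(p1[0])
    dc = float(p2[1]) - float(p1[1])
    dist_px = math.hypot(dr, dc)
    if dist_px == 0:
        raise DegenerateFiducialError(f"fiducial endpoints coincide at {tuple(p1)}")
    return CalibrationResult(
        mm_per_pixel=known_length_mm / dist_px,
        fiducial_p1=(float(p1[0]), float(p1[1])),
        fiducial_p2=(float(p2[0]), float(p2[1])),
        known_length_mm=float(known_length_mm),
    )


def scaled_area(pixel_count: float, cal: CalibrationResult) -> float:
    """Convert a pixel count to mm² via the calibrated pixel area."""
    if pixel_count < 0:
        raise ValueError(f"pixel_count must be non-negative, got {pixel_count}")
    return float(pixel_count) * cal.pixel_area_mm2
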