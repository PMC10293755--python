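"""Thermal-spread measurement: threshold segmentation over a thermogram sequence.

The headline quantity is the CUMULATIVE spread: the area of all pixels whose
temperature EVER exceeds the threshold anywhere in the sequence (strict ``>``).
The per-frame area series is reported alongside so the per-frame reading is
recoverable.  Default threshold: 60 °C.  Documented presets: 45 °C (hemostasis
onset) and the 57–65 °C protein-denaturation band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .calibration import CalibrationResult, scaled_area
from .errors import SequenceFormatError
from .io import ThermogramFrame, ThermogramSequence

__all__ = [
    "BinaryMask",
    "SpreadResult",
    "threshold_mask",
    "cumulative_mask",
    "analyze_spread",
    "largest_component_area",
    "DEFAULT_THRESHOLD_C",
    "THRESHOLD_PRESETS_C",
]

DEFAULT_THRESHOLD_C = 60.0
THRESHOLD_PRESETS_C = {
    "necrosis": 60.0,
    "hemostasis_onset": 45.0,
    "denaturation_low": 57.0,
    "denaturation_high": 65.0,
}


@dataclass(frozen=True)
class BinaryMask:
    """Boolean segmentation mask with the threshold that produced it."""

    values: np.ndarray
    threshold_c: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=bool)
        if arr.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {arr.shape}")
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def pixel_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class SpreadResult:
    """Cumulative >threshold area plus the per-frame series and peak temperature."""

    cumulative_area_mm2: float
    per_frame_area_mm2: pd.Series  # indexed by timestamp (s)
    peak_temperature_c: float
    threshold_c: float
    calibration: CalibrationResult
    mask: BinaryMask


def threshold_mask(frame: ThermogramFrame, threshold_c: float) -> BinaryMask:
    """Pixels strictly greater than ``threshold_c`` (a value equal to the
    threshold is NOT marked)."""
    values = frame.values
    if not np.all(np.isfinite(values)):
        raise SequenceFormatError("frame contains non-finite temperatures")
    return BinaryMask(values=values > threshold_c, threshold_c=float(threshold_c))


def cumulative_mask(
    seq: ThermogramSequence, threshold_c: float, min_frames_above: int = 1
) -> BinaryMask:
    """Union over frames: a pixel is marked if it EVER exceeds the threshold.

    ``min_frames_above`` (default 1 — plain union) optionally debounces
    single-frame sensor-noise flickers by requiring a pixel to exceed the
    threshold in at least that many frames.
    """
    if len(seq) == 0:  # unreachable through the type's invariant; belt and braces
        raise ValueError("empty sequence")
    if min_frames_above < 1:
        raise ValueError("min_frames_above must be >= 1")
    counts = np.zeros(seq.shape, dtype=np.int64)
    for frame in seq.frames:
        counts += frame.values > threshold_c
    return BinaryMask(values=counts >= min_frames_above, threshold_c=float(threshold_c))


def analyze_spread(
    seq: ThermogramSequence,
    cal: CalibrationResult,
    threshold_c: float = DEFAULT_THRESHOLD_C,
    min_frames_above: int = 1,
) -> SpreadResult:
    """Measure the thermal spread of a sequence.

    Returns the cumulative area (mm²) of ever-exceeding pixels, the per-frame
    area series (same scaling), and the global peak temperature.
    """
    cum = cumulative_mask(seq, threshold_c, min_frames_above=min_frames_above)
    per_frame = pd.Series(
        [scaled_area(threshold_mask(f, threshold_c).pixel_count, cal) for f in seq.frames],
        index=pd.Index(seq.timestamps, name="timestamp_s"),
        name="area_mm2",
    )
    peak = float(max(f.values.max() for f in seq.frames))
    return SpreadResult(
        cumulative_area_mm2=scaled_area(cum.pixel_count, cal),
        per_frame_area_mm2=per_frame,
        peak_temperature_c=peak,
        threshold_c=float(threshold_c),
        calibration=cal,
        mask=cum,
    )


def largest_component_area(mask: BinaryMask, cal: CalibrationResult) -> float:
    """Area (mm²) of the largest 4-connected component of the mask.

    Optional robustness filter; not applied by default anywhere.
    """
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    labels, n = ndimage.label(mask.values, structure=structure)
    if n == 0:
        return 0.0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return scaled_area(int(sizes.max()), cal)
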