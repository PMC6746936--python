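"""Gray-level to areal-BMD calibration.

DXA scanners report mean areal BMD only over three standard regions of
interest (neck, trochanter, intertrochanter), not per pixel.  Assuming gray
levels are linear in areal BMD, each ROI yields one line: the intercept is
postulated as a fraction ``f`` of the ROI mean aBMD (the unknown minimum BMD
in the region), and the slope follows from forcing the mean non-zero gray of
the ROI to map exactly onto the reported mean aBMD.  The three per-ROI lines
are averaged into a single patient-specific relation which is then applied
pixel-by-pixel inside the femur mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ROI_NAMES = ("neck", "trochanter", "intertrochanter")


@dataclass(frozen=True)
class GrayImage:
    """2D gray-level field with physical pixel spacing.

    Background is encoded as exactly 0; foreground grays are >= 0.
    """

    pixels: np.ndarray  # (rows, cols) float or int, non-negative
    spacing_mm: float

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("pixel spacing must be > 0")
        if np.any(np.asarray(self.pixels) < 0):
            raise ValueError("gray levels must be non-negative")


@dataclass(frozen=True)
class RoiMeasurement:
    """A named ROI mask and its scanner-reported mean areal BMD (g/cm^2)."""

    name: str
    mask: np.ndarray  # boolean
    mean_abmd: float

    def __post_init__(self) -> None:
        if not np.any(self.mask):
            raise ValueError(f"ROI {self.name!r}: empty mask")
        if self.mean_abmd <= 0:
            raise ValueError(f"ROI {self.name!r}: mean aBMD must be > 0")


@dataclass(frozen=True)
class CalibrationLine:
    """aBMD = intercept_b + slope_m * gray, built with minimum-BMD fraction f."""

    intercept_b: float  # g/cm^2
    slope_m: float      # g/cm^2 per gray unit
    fraction_f: float

    def __call__(self, gray: np.ndarray | float) -> np.ndarray | float:
        return self.intercept_b + self.slope_m * np.asarray(gray, dtype=float)


def calibrate_single_roi(
    image: GrayImage, roi: RoiMeasurement, fraction_f: float
) -> CalibrationLine:
    """Fit the two-anchor line for one ROI.

    Anchor 1: gray 0 maps to ``fraction_f * mean_abmd`` (the intercept).
    Anchor 2: the mean of the non-zero grays in the mask maps to ``mean_abmd``.
    """
    if not (0.0 <= fraction_f < 1.0):
        raise ValueError("fraction_f must lie in [0, 1)")
    grays = np.asarray(image.pixels, dtype=float)[roi.mask]
    grays = grays[grays > 0]
    if grays.size == 0:
        raise ValueError(
            f"ROI {roi.name!r}: all grays are zero, slope undefined"
        )
    g_bar = float(grays.mean())
    intercept = fraction_f * roi.mean_abmd
    slope = roi.mean_abmd * (1.0 - fraction_f) / g_bar
    return CalibrationLine(intercept_b=intercept, slope_m=slope, fraction_f=fraction_f)


def combine_rois(lines: list[CalibrationLine]) -> CalibrationLine:
    """Average the three per-ROI lines into one patient-specific relation."""
    if len(lines) != 3:
        raise ValueError("expected exactly three per-ROI calibration lines")
    fractions = {line.fraction_f for line in lines}
    if len(fractions) != 1:
        raise ValueError("per-ROI lines were built with different fractions f")
    return CalibrationLine(
        intercept_b=float(np.mean([li.intercept_b for li in lines])),
        slope_m=float(np.mean([li.slope_m for li in lines])),
        fraction_f=lines[0].fraction_f,
    )


def calibrate(
    image: GrayImage,
    rois: dict[str, RoiMeasurement],
    fraction_f: float = 0.20,
) -> CalibrationLine:
    """Full patient calibration from the three named ROIs."""
    missing = set(ROI_NAMES) - set(rois)
    if missing:
        raise ValueError(f"missing ROI measurements: {sorted(missing)}")
    lines = [calibrate_single_roi(image, rois[name], fraction_f) for name in ROI_NAMES]
    return combine_rois(lines)


def apply_calibration(
    image: GrayImage, line: CalibrationLine, femur_mask: np.ndarray
) -> np.ndarray:
    """Map grays to areal BMD inside the femur mask.

    Returns a float array equal to ``line(gray)`` (clamped below at 0) on the
    foreground and NaN on the background.
    """
    if line.slope_m <= 0:
        raise ValueError("calibration slope must be > 0")
    mask = np.asarray(femur_mask, dtype=bool)
    abmd = np.full(np.asarray(image.pixels).shape, np.nan, dtype=float)
    mapped = line(np.asarray(image.pixels, dtype=float)[mask])
    abmd[mask] = np.maximum(mapped, 0.0)
    return abmd
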