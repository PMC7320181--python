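"""Display-conditioning step: DICOM rescale, window/level and thresholding.

The segmentation workflow thresholds the *windowed* 8-bit display image,
not the raw stored values, mirroring the usual viewer pipeline: stored
values are first mapped to physical intensities via the DICOM rescale
slope/intercept, then linearly windowed to the 8-bit display range, and
compartment threshold bands are expressed on that 0-255 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class WindowLevel:
    """Linear display mapping: ``window`` is the width, ``level`` the center.

    Intensities in ``[level - window/2, level + window/2]`` map linearly
    onto 0..255; values outside clip to the endpoints.
    """

    window: float
    level: float

    def __post_init__(self):
        if not self.window > 0:
            raise ConfigError(f"window width must be > 0, got {self.window}")


@dataclass(frozen=True)
class ThresholdRange:
    """Inclusive intensity band on the 8-bit display scale."""

    low: int
    high: int

    def __post_init__(self):
        if not (0 <= self.low <= self.high <= 255):
            raise ConfigError(
                f"threshold range must satisfy 0 <= low <= high <= 255, "
                f"got [{self.low}, {self.high}]"
            )


def apply_rescale(img) -> np.ndarray:
    """Map stored pixel values to physical intensities.

    ``value = stored * rescale_slope + rescale_intercept`` elementwise,
    the standard DICOM modality rescale.
    """
    return img.pixels.astype(np.float64) * img.rescale_slope + img.rescale_intercept


def window_level(intensity: np.ndarray, wl: WindowLevel) -> np.ndarray:
    """Window an intensity grid to an 8-bit display grid.

    ``out = round_half_up(255 * clip((v - (level - window/2)) / window, 0, 1))``.
    Returns a uint8 array. Monotone non-decreasing in the input value.
    """
    if not wl.window > 0:
        raise ConfigError(f"window width must be > 0, got {wl.window}")
    v = np.asarray(intensity, dtype=np.float64)
    frac = np.clip((v - (wl.level - wl.window / 2.0)) / wl.window, 0.0, 1.0)
    # half-up rounding: floor(x + 0.5)
    return np.floor(255.0 * frac + 0.5).astype(np.uint8)


def threshold_mask(display: np.ndarray, rng: ThresholdRange) -> np.ndarray:
    """Boolean mask of display pixels inside the inclusive band [low, high]."""
    d = np.asarray(display)
    if d.dtype != np.uint8 and (d.min() < 0 or d.max() > 255):
        raise DataError("threshold_mask expects an 8-bit display grid (values 0..255)")
    return (d >= rng.low) & (d <= rng.high)
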