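"""Area quantification in mm² and the muscle-to-fat ratio indexes.

Areas are pixel counts scaled by the in-plane pixel spacing. The three
ratio indexes MA/SA, MA/VA and MA/(SA+VA) relate cross-sectional muscle
area to subcutaneous, visceral and total fat area; low values indicate
relatively low muscle mass for the amount of fat, the pattern of
sarcopenic obesity. A ratio whose denominator is zero is explicitly
undefined (carried as ``None`` with a reason), never 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .segmentation import LabelMap
from .util import round_half_up

RATIO_NAMES = ("MA_SA", "MA_VA", "MA_SAVA")


@dataclass(frozen=True)
class CompartmentAreas:
    """Cross-sectional areas in mm²: muscle (MA), subcutaneous fat (SA),
    visceral fat (VA)."""

    MA: float
    SA: float
    VA: float

    def __post_init__(self):
        for name in ("MA", "SA", "VA"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RatioSet:
    """The three ratio indexes; ``None`` marks an undefined ratio.

    ``reasons`` explains each undefined entry. When all three are
    defined they satisfy 1/MA_SAVA = 1/MA_SA + 1/MA_VA.
    """

    MA_SA: float | None
    MA_VA: float | None
    MA_SAVA: float | None
    reasons: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"MA_SA": self.MA_SA, "MA_VA": self.MA_VA, "MA_SAVA": self.MA_SAVA}


def area_mm2(mask: np.ndarray, row_spacing: float, col_spacing: float) -> float:
    """Area of a binary mask: true-pixel count × pixel area in mm²."""
    if row_spacing <= 0 or col_spacing <= 0:
        raise ConfigError(
            f"pixel spacing must be positive, got {row_spacing} x {col_spacing} mm"
        )
    return float(np.count_nonzero(mask)) * row_spacing * col_spacing


def compute_areas(label_map: LabelMap, row_spacing: float,
                  col_spacing: float) -> CompartmentAreas:
    """Per-compartment areas of a label map; absent compartments give 0."""
    return CompartmentAreas(
        MA=area_mm2(label_map.mask("M"), row_spacing, col_spacing),
        SA=area_mm2(label_map.mask("S"), row_spacing, col_spacing),
        VA=area_mm2(label_map.mask("V"), row_spacing, col_spacing),
    )


def compute_ratios(areas: CompartmentAreas) -> RatioSet:
    """Ratio indexes MA/SA, MA/VA, MA/(SA+VA) from compartment areas."""
    reasons: dict = {}

    def safe(num: float, den: float, name: str, what: str) -> float | None:
        if den > 0:
            return num / den
        reasons[name] = f"undefined: {what} is zero"
        return None

    return RatioSet(
        MA_SA=safe(areas.MA, areas.SA, "MA_SA", "subcutaneous fat area"),
        MA_VA=safe(areas.MA, areas.VA, "MA_VA", "visceral fat area"),
        MA_SAVA=safe(areas.MA, areas.SA + areas.VA, "MA_SAVA", "total fat area"),
        reasons=reasons,
    )


def format_area(value: float) -> str:
    """Area formatted for printed summaries: half-up at 1 decimal."""
    return f"{round_half_up(value, 1):.1f}"


def format_ratio(value: float | None) -> str:
    """Ratio formatted for printed summaries: half-up at 1 decimal."""
    return "undefined" if value is None else f"{round_half_up(value, 1):.1f}"
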